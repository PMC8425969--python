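"""Model-free statistics on the simulated cohort.

Reads results/cohort.csv and writes: per-subject behavioral summary, the
PPI mixed ANOVA (group x block), the accuracy mixed ANOVA (group x block x
congruency x valence), estimation statistics for the three intervention
arms against the shared HighControl-Sham control, and the stimulated-vs-
sham comparison of block difference scores.
"""

from pathlib import Path

from gonogo.io import read_trial_table
from gonogo.metrics import (accuracy_long, behavioral_summary,
                            block_difference_effects, mixed_anova,
                            shared_control_effects)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2027


def main() -> None:
    table = read_trial_table(RESULTS / "cohort.csv")
    summary = behavioral_summary(table)
    summary["group"] = summary["control"] + "_" + summary["tdcs"]
    summary.to_csv(RESULTS / "subject_summary.csv", index=False)

    anova_ppi = mixed_anova(summary.dropna(subset=["ppi"]), dv="ppi",
                            subject="subject_id", between="group",
                            within=["block"])
    anova_ppi.to_csv(RESULTS / "anova_ppi.csv", index=False)
    print("PPI mixed ANOVA (group x block):")
    print(anova_ppi[["effect", "F", "df1", "df2", "p", "partial_eta_sq"]]
          .round(4).to_string(index=False))

    acc = accuracy_long(table)
    anova_acc = mixed_anova(acc, dv="accuracy", subject="subject_id",
                            between="group",
                            within=["block", "congruency", "valence"])
    anova_acc.to_csv(RESULTS / "anova_accuracy.csv", index=False)
    blk_grp = anova_acc.set_index("effect").loc["block * group"]
    print(f"\naccuracy block x group: F({blk_grp['df1']:.0f},{blk_grp['df2']:.0f})"
          f" = {blk_grp['F']:.2f}, p = {blk_grp['p']:.4f}")

    shared = shared_control_effects(summary, "ppi", seed=SEED)
    shared.to_csv(RESULTS / "effects_ppi_vs_control.csv", index=False)
    print("\nPPI vs shared control (Cohen's d, BCa 95% CI):")
    print(shared.round(3).to_string(index=False))

    diffs = block_difference_effects(summary, "accuracy", seed=SEED)
    diffs.to_csv(RESULTS / "effects_accuracy_block_diff.csv", index=False)
    print("\naccuracy block2-block1, stimulated vs sham:")
    print(diffs.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
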