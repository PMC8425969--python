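"""Model-free behavioral statistics for the Go/NoGo task.

Covers the standard model-free analyses of this paradigm: the Pavlovian performance
index (PPI) and its two sub-measures, per-card accuracy and Go-percentage
tables, the mixed between-within ANOVA with partial eta squared and
Bonferroni pairwise correction, and estimation statistics (unpaired
Cohen's d with bias-corrected and accelerated bootstrap intervals).

Definitions
-----------
reward-based invigoration
    (# Go responses on Win-valence trials) / (# Go responses overall);
    undefined (NaN) when a subject never pressed Go in the block.
punishment-based suppression
    (# NoGo responses on Avoid-valence trials) / (# NoGo responses
    overall); undefined when the subject always pressed Go.
PPI
    mean of the two sub-measures; 0.5 is the neutral baseline on a
    balanced block, 1.0 is a purely Pavlovian responder.  Undefined
    sub-measures propagate as missing rather than being clamped.

The mixed ANOVA is the classical split-plot analysis specialised to
two-level within factors: each within effect maps to an orthonormal
contrast score per subject, and every stratum is tested by an ordinary
between-subjects linear model (Type III, sum-coded groups).  With
two-level factors sphericity holds exactly, so no correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .task import Card

__all__ = [
    "invigoration",
    "suppression",
    "ppi",
    "accuracy_and_percgo",
    "behavioral_summary",
    "mixed_anova",
    "cohens_d",
    "cohens_d_bca",
    "bonferroni_pairwise",
    "EffectSize",
    "shared_control_effects",
    "block_difference_effects",
    "GROUP_ORDER",
]

#: canonical (control, tdcs) order; HighControl-Sham is the shared control arm
GROUP_ORDER = (("high", "sham"), ("high", "stim"), ("low", "sham"), ("low", "stim"))


def _valence(card: str) -> str:
    return Card(card).valence


def invigoration(records: pd.DataFrame) -> float:
    """Reward-based invigoration for one subject-block; NaN when no Go at all."""
    is_go = records["response"] == "go"
    n_go = int(is_go.sum())
    if n_go == 0:
        return float("nan")
    on_win = records["card"].map(_valence) == "win"
    return float((is_go & on_win).sum() / n_go)


def suppression(records: pd.DataFrame) -> float:
    """Punishment-based suppression; NaN when the subject never pressed NoGo."""
    is_nogo = records["response"] == "nogo"
    n_nogo = int(is_nogo.sum())
    if n_nogo == 0:
        return float("nan")
    on_avoid = records["card"].map(_valence) == "avoid"
    return float((is_nogo & on_avoid).sum() / n_nogo)


def ppi(records: pd.DataFrame) -> float:
    """Pavlovian performance index: mean of invigoration and suppression.

    Missing (all-Go or all-NoGo) sub-measures propagate: the PPI is NaN
    whenever either sub-measure is undefined.
    """
    return (invigoration(records) + suppression(records)) / 2.0


def accuracy_and_percgo(records: pd.DataFrame) -> pd.DataFrame:
    """Per card type: response accuracy and percentage of Go responses."""
    rows = []
    for card in Card:
        sub = records[records["card"] == card.value]
        if len(sub) == 0:
            continue
        rows.append({"card": card.value, "valence": card.valence,
                     "congruent": card.congruent,
                     "accuracy": float(sub["correct"].mean()),
                     "perc_go": float((sub["response"] == "go").mean()),
                     "n_trials": len(sub)})
    return pd.DataFrame(rows)


def behavioral_summary(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Subject x block summary: PPI, sub-measures, per-card accuracy and PercGo."""
    rows = []
    for (sid, block), grp in trial_table.groupby(["subject_id", "block"], sort=True):
        row = {"subject_id": sid,
               "control": grp["control"].iloc[0], "tdcs": grp["tdcs"].iloc[0],
               "block": block,
               "invigoration": invigoration(grp), "suppression": suppression(grp),
               "ppi": ppi(grp), "accuracy": float(grp["correct"].mean())}
        for rec in accuracy_and_percgo(grp).itertuples():
            row[f"accuracy_{rec.card}"] = rec.accuracy
            row[f"perc_go_{rec.card}"] = rec.perc_go
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_long(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-card accuracy with congruency and valence factors.

    One row per subject x block x card; input to the accuracy mixed ANOVA
    with within factors block, congruency and valence.
    """
    rows = []
    for (sid, block, card), grp in trial_table.groupby(["subject_id", "block", "card"],
                                                       sort=True):
        c = Card(card)
        rows.append({"subject_id": sid, "control": grp["control"].iloc[0],
                     "tdcs": grp["tdcs"].iloc[0],
                     "group": grp["control"].iloc[0] + "_" + grp["tdcs"].iloc[0],
                     "block": block, "card": card, "valence": c.valence,
                     "congruency": "congruent" if c.congruent else "conflict",
                     "accuracy": float(grp["correct"].mean()),
                     "perc_go": float((grp["response"] == "go").mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed between-within ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(data: pd.DataFrame, dv: str, subject: str, between: str,
                within: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Mixed ANOVA with one between factor and up to three 2-level within factors.

    Requires a complete balanced within design (every subject contributes
    exactly one value in every within cell); violations raise ValueError
    naming the offending subjects.  Returns one row per effect with F,
    degrees of freedom, p and partial eta squared
    (SS_effect / (SS_effect + SS_error) within the effect's stratum).
    """
    within = list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("need between one and three within factors")
    levels = {f: sorted(data[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"within factor {f!r} must have exactly 2 levels, got {lv}")

    cells = list(product(*[levels[f] for f in within]))
    cell_pos = {c: j for j, c in enumerate(cells)}
    subjects = sorted(data[subject].unique())
    subj_pos = {s: i for i, s in enumerate(subjects)}
    n_cells = len(cells)
    Y = np.full((len(subjects), n_cells), np.nan)
    count = np.zeros_like(Y)
    group_of = {}
    for rec in data.itertuples(index=False):
        d = rec._asdict()
        i = subj_pos[d[subject]]
        j = cell_pos[tuple(d[f] for f in within)]
        Y[i, j] = d[dv]
        count[i, j] += 1
        g = d[between]
        if group_of.setdefault(d[subject], g) != g:
            raise ValueError(f"subject {d[subject]!r} appears in more than one "
                             f"{between} group")
    if (count > 1).any():
        bad = [subjects[i] for i in sorted(set(np.nonzero(count > 1)[0]))]
        raise ValueError(f"duplicate within-cell observations for subjects: {bad}")
    if np.isnan(Y).any():
        bad = [subjects[i] for i in sorted(set(np.nonzero(np.isnan(Y))[0]))]
        raise ValueError(f"incomplete within design for subjects: {bad}")
    groups = np.array([group_of[s] for s in subjects])

    codes = {f: {levels[f][0]: 1.0, levels[f][1]: -1.0} for f in within}

    rows = []
    for k in range(0, len(within) + 1):
        for effect_factors in combinations(within, k):
            h = np.array([np.prod([codes[f][cell[within.index(f)]]
                                   for f in effect_factors])
                          for cell in cells], dtype=float) / np.sqrt(n_cells)
            score = Y @ h
            frame = pd.DataFrame({"score": score, "grp": groups})
            model = smf.ols("score ~ C(grp, Sum)", data=frame).fit()
            table = sm.stats.anova_lm(model, typ=3)
            ss_err = float(table.loc["Residual", "sum_sq"])
            df_err = float(table.loc["Residual", "df"])
            entries = []
            if effect_factors:
                name = " * ".join(effect_factors)
                entries.append((name, "Intercept"))
                entries.append((f"{name} * {between}", "C(grp, Sum)"))
            else:
                entries.append((between, "C(grp, Sum)"))
            for name, key in entries:
                ss = float(table.loc[key, "sum_sq"])
                df1 = float(table.loc[key, "df"])
                with np.errstate(divide="ignore", invalid="ignore"):
                    F = (ss / df1) / (ss_err / df_err) if df_err > 0 else np.nan
                    p = stats.f.sf(F, df1, df_err) if np.isfinite(F) else np.nan
                    eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan
                rows.append({"effect": name, "F": F, "df1": df1, "df2": df_err,
                             "p": p, "partial_eta_sq": eta,
                             "ss_effect": ss, "ss_error": ss_err})
    return pd.DataFrame(rows)


def bonferroni_pairwise(p_values, family_size: int | None = None):
    """Bonferroni adjustment: raw p times the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    out = np.minimum(p * m, 1.0)
    return float(out) if np.isscalar(p_values) else out


# ---------------------------------------------------------------------------
# estimation statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """Unpaired Cohen's d (sign convention a - b) with a BCa bootstrap CI."""

    d: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    degenerate: bool = False


def cohens_d(a, b, axis: int = -1) -> float | np.ndarray:
    """Unpaired Cohen's d with the pooled standard deviation, sign a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=axis) - b.mean(axis=axis)) / pooled


def cohens_d_bca(a, b, n_boot: int = 5000, mass: float = 0.95,
                 seed: int | None = None) -> EffectSize:
    """Cohen's d with a bias-corrected and accelerated bootstrap interval.

    Both samples are resampled independently (unpaired design); the
    acceleration constant comes from the jackknife.  Deterministic given
    the seed.  A zero pooled variance is flagged as degenerate instead of
    producing an interval.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    point = float(cohens_d(a, b))
    if not np.isfinite(point):
        return EffectSize(d=point, ci_low=float("nan"), ci_high=float("nan"),
                          n_boot=n_boot, seed=seed, degenerate=True)
    res = stats.bootstrap((a, b), cohens_d, n_resamples=n_boot,
                          confidence_level=mass, method="BCa", vectorized=True,
                          rng=np.random.default_rng(seed))
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    return EffectSize(d=point, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed,
                      degenerate=not (np.isfinite(lo) and np.isfinite(hi)))


def shared_control_effects(summary: pd.DataFrame, value: str = "ppi",
                           control_group: tuple[str, str] = ("high", "sham"),
                           n_boot: int = 5000, seed: int | None = None) -> pd.DataFrame:
    """Each intervention arm vs a shared control arm, separately per block.

    The estimation-plot layout of the analysis: Cohen's d (arm minus
    control) with BCa intervals for the three groups receiving an
    experimental intervention against HighControl-Sham.
    """
    rows = []
    ctrl_c, ctrl_t = control_group
    for block, blk in summary.groupby("block", sort=True):
        ref = blk[(blk["control"] == ctrl_c) & (blk["tdcs"] == ctrl_t)][value].dropna()
        for control, tdcs in GROUP_ORDER:
            if (control, tdcs) == control_group:
                continue
            arm = blk[(blk["control"] == control) & (blk["tdcs"] == tdcs)][value].dropna()
            es = cohens_d_bca(arm.to_numpy(), ref.to_numpy(), n_boot=n_boot, seed=seed)
            rows.append({"block": block, "group": f"{control}_{tdcs}",
                         "vs": f"{ctrl_c}_{ctrl_t}", "measure": value,
                         "d": es.d, "ci_low": es.ci_low, "ci_high": es.ci_high,
                         "n": len(arm), "n_control": len(ref)})
    return pd.DataFrame(rows)


def block_difference_effects(summary: pd.DataFrame, value: str = "accuracy",
                             n_boot: int = 5000, seed: int | None = None) -> pd.DataFrame:
    """Stimulated vs sham comparison of block2 - block1 difference scores.

    Computed separately within the HighControl and LowControl conditions;
    positive d means a larger block-to-block change under stimulation.
    """
    wide = summary.pivot_table(index=["subject_id", "control", "tdcs"],
                               columns="block", values=value).reset_index()
    wide["diff"] = wide[2] - wide[1]
    rows = []
    for control, grp in wide.groupby("control", sort=True):
        stim = grp[grp["tdcs"] == "stim"]["diff"].dropna().to_numpy()
        sham = grp[grp["tdcs"] == "sham"]["diff"].dropna().to_numpy()
        es = cohens_d_bca(stim, sham, n_boot=n_boot, seed=seed)
        rows.append({"control": control, "measure": value, "d": es.d,
                     "ci_low": es.ci_low, "ci_high": es.ci_high,
                     "n_stim": len(stim), "n_sham": len(sham)})
    return pd.DataFrame(rows)
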