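"""Behavioral metrics: PPI, accuracy tables, mixed ANOVA, estimation statistics."""

import numpy as np
import pandas as pd
import pytest
from conftest import forced_session, pavlovian_session
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo.metrics import (accuracy_and_percgo, behavioral_summary,
                            block_difference_effects, bonferroni_pairwise, cohens_d,
                            cohens_d_bca, invigoration, mixed_anova, ppi,
                            shared_control_effects, suppression)


class TestPpi:
    def test_always_go_agent_is_neutral(self):
        df = forced_session("go")
        assert invigoration(df) == pytest.approx(0.5)  # 80 Win-Go / 160 Go
        assert np.isnan(suppression(df))
        assert np.isnan(ppi(df))

    def test_always_nogo_agent(self):
        df = forced_session("nogo")
        assert suppression(df) == pytest.approx(0.5)
        assert np.isnan(invigoration(df))

    def test_pure_pavlovian_agent_scores_one(self):
        df = pavlovian_session()
        assert invigoration(df) == 1.0
        assert suppression(df) == 1.0
        assert ppi(df) == 1.0

    def test_perfectly_instrumental_agent_is_neutral(self):
        from gonogo.task import (TRIAL_COLUMNS, Card, apply_go_cost,
                                 make_block_schedule, resolve_outcome)

        rows = []
        for t, trial in enumerate(make_block_schedule(40, 0.7, 3)):
            response = trial.card.required_action
            base = resolve_outcome(trial.card, response, trial.favorable)
            rows.append(("i0", "high", "sham", 1, t, trial.card.value, response,
                         base, apply_go_cost(base, response), 1))
        df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
        assert ppi(df) == pytest.approx(0.5)

    def test_trial_order_invariance(self, one_session):
        block = one_session[one_session["block"] == 1]
        shuffled = block.sample(frac=1.0, random_state=0)
        assert invigoration(shuffled) == invigoration(block)
        assert suppression(shuffled) == suppression(block)

    def test_ppi_monotone_in_generating_pi(self):
        from gonogo.model import AgentParams, simulate_agent
        from gonogo.task import make_block_schedule

        sch = {1: make_block_schedule(250, 0.7, 9, block=1)}
        values = []
        for pi_true in (-1.0, 0.0, 1.0, 3.0):
            df = simulate_agent({1: AgentParams(0.3, 0.8, pi_true, 0.0)}, sch, 17)
            values.append(ppi(df))
        assert all(a < b for a, b in zip(values, values[1:]))


class TestAccuracyTables:
    def test_always_go_responder(self):
        table = accuracy_and_percgo(forced_session("go")).set_index("card")
        assert (table["perc_go"] == 1.0).all()
        assert table.loc["go_win", "accuracy"] == 1.0
        assert table.loc["go_avoid", "accuracy"] == 1.0
        assert table.loc["nogo_win", "accuracy"] == 0.0
        assert table.loc["nogo_avoid", "accuracy"] == 0.0

    def test_accuracy_complements_error_rate(self, one_session):
        table = accuracy_and_percgo(one_session[one_session["block"] == 2])
        assert ((table["accuracy"] >= 0) & (table["accuracy"] <= 1)).all()
        assert table["n_trials"].sum() == 160

    def test_summary_has_one_row_per_subject_block(self, small_cohort):
        table, _ = small_cohort
        summary = behavioral_summary(table)
        assert len(summary) == 16 * 2
        assert {"invigoration", "suppression", "ppi", "accuracy_go_win"} <= \
            set(summary.columns)


def _toy_two_way():
    """4 subjects, 2 groups, 2 blocks; oracle computed with textbook formulas."""
    data = pd.DataFrame({
        "subject": ["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
        "grp": ["a", "a", "a", "a", "b", "b", "b", "b"],
        "block": [1, 2] * 4,
        "y": [3.0, 5.0, 4.0, 7.0, 6.0, 6.0, 7.0, 8.0],
    })
    return data


def _oracle_split_plot(data):
    """Straight-line textbook computation of the balanced 2x(2) split-plot."""
    y = data.pivot_table(index="subject", columns="block", values="y")
    groups = data.groupby("subject")["grp"].first().reindex(y.index)
    n, k = y.shape[0], 2
    grand = y.to_numpy().mean()
    subj_means = y.mean(axis=1)
    grp_means = subj_means.groupby(groups).mean()
    n_per_grp = subj_means.groupby(groups).size()
    ss_group = float((k * n_per_grp * (grp_means - grand) ** 2).sum())
    ss_subj_within = float((k * (subj_means - subj_means.groupby(groups)
                                 .transform("mean")) ** 2).sum())
    block_means = y.mean(axis=0)
    ss_block = float((n * (block_means - grand) ** 2).sum())
    cell_means = data.groupby(["grp", "block"])["y"].mean()
    ss_cells = float((n_per_grp.reindex(cell_means.index.get_level_values(0)).to_numpy()
                      * (cell_means.to_numpy() - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_group - ss_block
    ss_total = float(((y.to_numpy() - grand) ** 2).sum())
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_block - ss_interaction
    g = len(grp_means)
    return {
        "grp": (ss_group / (g - 1)) / (ss_subj_within / (n - g)),
        "block": (ss_block / 1) / (ss_err_within / (n - g)),
        "block * grp": (ss_interaction / 1) / (ss_err_within / (n - g)),
        "ss": (ss_group, ss_subj_within, ss_block, ss_interaction, ss_err_within,
               ss_total),
    }


class TestMixedAnova:
    def test_matches_textbook_split_plot_oracle(self):
        data = _toy_two_way()
        oracle = _oracle_split_plot(data)
        table = mixed_anova(data, dv="y", subject="subject", between="grp",
                            within=["block"]).set_index("effect")
        assert table.loc["grp", "F"] == pytest.approx(oracle["grp"])
        assert table.loc["block", "F"] == pytest.approx(oracle["block"])
        assert table.loc["block * grp", "F"] == pytest.approx(oracle["block * grp"])

    def test_ss_decomposition_is_exact(self):
        data = _toy_two_way()
        oracle = _oracle_split_plot(data)
        table = mixed_anova(data, dv="y", subject="subject", between="grp",
                            within=["block"])
        ss_total_from_effects = table["ss_effect"].sum() + \
            table.drop_duplicates("ss_error")["ss_error"].sum()
        assert ss_total_from_effects == pytest.approx(oracle["ss"][-1])

    def test_matches_pingouin_on_random_balanced_design(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for i in range(24):
            grp = ["a", "b", "c"][i % 3]
            base = rng.normal(0, 1)
            for block in (1, 2):
                rows.append({"subject": f"s{i}", "grp": grp, "block": block,
                             "y": base + rng.normal(0.3 * block, 1.0)})
        data = pd.DataFrame(rows)
        ours = mixed_anova(data, dv="y", subject="subject", between="grp",
                           within=["block"]).set_index("effect")
        theirs = pingouin.mixed_anova(data, dv="y", subject="subject",
                                      between="grp", within="block").set_index("Source")
        assert ours.loc["grp", "F"] == pytest.approx(theirs.loc["grp", "F"])
        assert ours.loc["block", "F"] == pytest.approx(theirs.loc["block", "F"])
        assert ours.loc["block * grp", "F"] == \
            pytest.approx(theirs.loc["Interaction", "F"])
        assert ours.loc["block", "p"] == pytest.approx(theirs.loc["block", "p_unc"])

    def test_three_within_factors_full_effect_list(self, small_cohort):
        from gonogo.metrics import accuracy_long

        table, _ = small_cohort
        acc = accuracy_long(table)
        res = mixed_anova(acc, dv="accuracy", subject="subject_id", between="group",
                          within=["block", "congruency", "valence"])
        # 2^3 strata: between + 7 within effects, each with its group interaction
        assert len(res) == 1 + 7 * 2
        assert set(res["df1"]) <= {1.0, 3.0}
        assert np.isfinite(res["partial_eta_sq"]).all()
        assert ((res["partial_eta_sq"] >= 0) & (res["partial_eta_sq"] <= 1)).all()

    def test_incomplete_design_names_subject(self):
        data = _toy_two_way().drop(index=3)
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(data, dv="y", subject="subject", between="grp",
                        within=["block"])

    def test_permutation_null_calibration(self):
        # type-I error of the group test ~ alpha on null data
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            data = pd.DataFrame({
                "subject": np.repeat([f"s{i}" for i in range(12)], 2),
                "grp": np.repeat(rng.permutation(["a"] * 6 + ["b"] * 6), 2),
                "block": [1, 2] * 12,
                "y": rng.normal(size=24),
            })
            table = mixed_anova(data, dv="y", subject="subject", between="grp",
                                within=["block"]).set_index("effect")
            hits += table.loc["grp", "p"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)


class TestBonferroni:
    def test_scaling_cap_and_identity(self):
        assert bonferroni_pairwise(0.01, 4) == pytest.approx(0.04)
        assert bonferroni_pairwise(0.5, 4) == 1.0
        assert bonferroni_pairwise(0.2, 1) == pytest.approx(0.2)
        np.testing.assert_allclose(bonferroni_pairwise([0.01, 0.5], 3), [0.03, 1.0])


class TestEffectSizes:
    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a.copy()) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        d = cohens_d(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        assert d == pytest.approx(-1.4142, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 30))
        b = rng.normal(0.5, 1.5, rng.integers(3, 30))
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_bca_interval_contains_estimate_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        es1 = cohens_d_bca(a, b, n_boot=2000, seed=11)
        es2 = cohens_d_bca(a, b, n_boot=2000, seed=11)
        assert (es1.ci_low, es1.ci_high) == (es2.ci_low, es2.ci_high)
        assert es1.ci_low < es1.d < es1.ci_high
        assert not es1.degenerate

    def test_bca_seed_stability(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.8, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        e1 = cohens_d_bca(a, b, n_boot=5000, seed=1)
        e2 = cohens_d_bca(a, b, n_boot=5000, seed=2)
        assert abs(e1.ci_low - e2.ci_low) < 0.05
        assert abs(e1.ci_high - e2.ci_high) < 0.05

    def test_degenerate_zero_variance_flagged(self):
        es = cohens_d_bca(np.ones(5), np.ones(6), n_boot=100, seed=0)
        assert es.degenerate

    def test_shared_control_and_block_difference_layout(self, small_cohort):
        table, _ = small_cohort
        summary = behavioral_summary(table)
        shared = shared_control_effects(summary, "ppi", n_boot=200, seed=3)
        assert len(shared) == 6  # 3 comparisons x 2 blocks
        assert set(shared["vs"]) == {"high_sham"}
        diffs = block_difference_effects(summary, "accuracy", n_boot=200, seed=3)
        assert list(diffs["control"]) == ["high", "low"]
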