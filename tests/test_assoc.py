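"""Contingency tables, odds ratios, logistic models, descriptive tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietclust import (contingency_by_cluster, crude_or,
                       descriptive_compare, fit_models, likelihood_ratio_p,
                       model_specs, or_results_frame)
from dietclust.assoc import (ContingencyTable2xK, MODEL_SPECS,
                             SeparationError, default_reference)

# The study's printed 2x4 table: cases / cluster sizes
PRINTED = dict(clusters=["A", "B", "C", "D"],
               cases=[6, 17, 9, 32],
               non_cases=[69, 113, 91, 110],
               reference="D")


@pytest.fixture
def printed_table():
    return ContingencyTable2xK(**PRINTED)


class TestContingency:
    def test_printed_prevalences(self, printed_table):
        prev = printed_table.prevalence_pct
        assert prev["A"] == pytest.approx(8.00, abs=0.005)
        assert prev["B"] == pytest.approx(13.08, abs=0.005)
        assert prev["C"] == pytest.approx(9.00, abs=0.005)
        assert prev["D"] == pytest.approx(22.53, abs=0.01)

    def test_reference_rule_largest_then_most_prevalent(self):
        sizes = pd.Series({"A": 75, "B": 130, "C": 100, "D": 142})
        prev = pd.Series({"A": 0.08, "B": 0.13, "C": 0.09, "D": 0.225})
        assert default_reference(sizes, prev) == "D"

    def test_from_arrays(self):
        outcome = np.array([1, 0, 0, 1, 1, 0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        table = contingency_by_cluster(outcome, labels)
        assert table.cases.tolist() == [1, 2]
        assert table.sizes.tolist() == [3, 3]

    def test_zero_cases_everywhere(self):
        table = contingency_by_cluster(np.zeros(10, dtype=int),
                                       np.repeat([0, 1], 5))
        assert (table.prevalence_pct == 0).all()

    def test_single_cluster_margins(self):
        table = contingency_by_cluster(np.array([1, 0, 1]),
                                       np.zeros(3, dtype=int))
        assert table.sizes.tolist() == [3]

    def test_unassigned_errors(self):
        with pytest.raises(ValueError, match="label"):
            contingency_by_cluster(np.array([1.0, 0.0]),
                                   np.array([0.0, np.nan]))


class TestCrudeOR:
    def test_printed_odds_ratios_and_cis(self, printed_table):
        results = {r.contrast: r for r in crude_or(printed_table)}
        assert results["A"].odds_ratio == pytest.approx(0.299, abs=5e-4)
        assert results["B"].odds_ratio == pytest.approx(0.517, abs=5e-4)
        assert results["C"].odds_ratio == pytest.approx(0.340, abs=5e-4)
        assert results["A"].ci_low == pytest.approx(0.12, abs=0.005)
        assert results["A"].ci_high == pytest.approx(0.75, abs=0.005)
        assert results["B"].ci_low == pytest.approx(0.272, abs=0.002)
        assert results["B"].ci_high == pytest.approx(0.984, abs=0.002)
        assert results["C"].ci_low == pytest.approx(0.154, abs=0.002)
        assert results["C"].ci_high == pytest.approx(0.749, abs=0.002)

    def test_equal_proportions_or_one(self):
        table = ContingencyTable2xK(["X", "Y"], [10, 20], [40, 80],
                                    reference="Y")
        (res,) = crude_or(table)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_reference_swap_inverts(self, printed_table):
        swapped = ContingencyTable2xK(**{**PRINTED, "reference": "A"})
        res_d = {r.contrast: r for r in crude_or(printed_table)}
        res_a = {r.contrast: r for r in crude_or(swapped)}
        assert res_a["D"].odds_ratio == pytest.approx(
            1 / res_d["A"].odds_ratio)
        assert res_a["D"].ci_low == pytest.approx(1 / res_d["A"].ci_high)
        assert res_a["D"].ci_high == pytest.approx(1 / res_d["A"].ci_low)

    def test_zero_cell_errors_unless_corrected(self):
        table = ContingencyTable2xK(["X", "Y"], [0, 5], [20, 15],
                                    reference="Y")
        with pytest.raises(ValueError, match="zero cell"):
            crude_or(table)
        (res,) = crude_or(table, continuity_correction=True)
        assert res.odds_ratio == pytest.approx(
            (0.5 * 15.5) / (20.5 * 5.5))


class TestLikelihoodRatio:
    def test_printed_table_g2_p(self, printed_table):
        # G2 = 2 sum O ln(O/E), 3 df, on the printed counts
        p = likelihood_ratio_p(printed_table)
        assert p == pytest.approx(0.006, abs=5e-4)

    def test_matches_hand_g2(self, printed_table):
        obs = np.array([[6, 17, 9, 32], [69, 113, 91, 110]], dtype=float)
        expected = (obs.sum(axis=1, keepdims=True)
                    * obs.sum(axis=0, keepdims=True) / obs.sum())
        g2 = 2 * np.sum(obs * np.log(obs / expected))
        assert likelihood_ratio_p(printed_table) == pytest.approx(
            stats.chi2.sf(g2, 3), rel=1e-12)


def _cluster_frame(cases, sizes, seed=0):
    """Participant-level frame realizing exact contingency counts."""
    labels, y = [], []
    for c, (n_case, n) in enumerate(zip(cases, sizes)):
        labels += [c] * n
        y += [1] * n_case + [0] * (n - n_case)
    df = pd.DataFrame({"incident_hypertension": y})
    return df, np.array(labels)


class TestFitModels:
    def test_crude_model_matches_closed_form(self, printed_table):
        df, labels = _cluster_frame([6, 17, 9, 32], [75, 130, 100, 142])
        results = fit_models(df, labels, model_specs(["Model 1"]),
                             reference=3)
        closed = {r.contrast: r for r in crude_or(printed_table)}
        mapping = dict(zip([0, 1, 2], ["A", "B", "C"]))
        for r in results:
            ref = closed[mapping[r.contrast]]
            assert r.odds_ratio == pytest.approx(ref.odds_ratio, abs=1e-6)
            assert r.ci_low == pytest.approx(ref.ci_low, abs=1e-6)
            assert r.ci_high == pytest.approx(ref.ci_high, abs=1e-6)
            assert r.lr_p == pytest.approx(ref.lr_p, abs=1e-9)

    def test_nested_deviance_non_increasing(self, preset_cohort):
        cohort, latent = preset_cohort
        import statsmodels.api as sm
        from dietclust.assoc import _design, _fit_logit
        y = cohort.data["incident_hypertension"].astype(int).to_numpy()
        labels = pd.Series(latent.to_numpy(), index=cohort.data.index)
        prev = None
        for spec in MODEL_SPECS:
            X, _ = _design(cohort.data, labels, 3, spec)
            res = _fit_logit(y, X)
            if prev is not None:
                assert res.llf >= prev - 1e-8
            prev = res.llf

    def test_null_lr_p_uniform(self):
        """With no cluster effect, the LR p is uniform over replicates."""
        rng = np.random.default_rng(12345)
        pvals = []
        for _ in range(200):
            labels = rng.integers(0, 4, size=400)
            y = (rng.uniform(size=400) < 0.15).astype(int)
            df = pd.DataFrame({"incident_hypertension": y})
            try:
                res = fit_models(df, labels, model_specs(["Model 1"]),
                                 reference=3)
            except SeparationError:
                continue
            pvals.append(res[0].lr_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_separation_detected(self):
        df = pd.DataFrame({
            "incident_hypertension": [1] * 10 + [0] * 10,
            "age": [60.0] * 10 + [30.0] * 10,
        })
        labels = np.array([0] * 10 + [1] * 10)
        with pytest.raises(SeparationError):
            fit_models(df, labels, model_specs(["Model 1"]), reference=1)

    def test_adjusted_models_run_on_preset(self, preset_cohort):
        cohort, latent = preset_cohort
        results = fit_models(cohort.data, latent.to_numpy(),
                             model_specs(), reference=3)
        frame = or_results_frame(results)
        assert set(frame["model"]) == {s.name for s in MODEL_SPECS}
        assert (frame["ci_low"] <= frame["OR"]).all()
        assert (frame["OR"] <= frame["ci_high"]).all()


class TestDescriptiveCompare:
    def test_planted_categorical_difference(self):
        # diabetes counts (0, 2, 1, 14) of (75, 130, 100, 142)
        labels, flag = [], []
        for c, (n_pos, n) in enumerate(zip([0, 2, 1, 14],
                                           [75, 130, 100, 142])):
            labels += [c] * n
            flag += [True] * n_pos + [False] * (n - n_pos)
        df = pd.DataFrame({"diabetes": flag})
        res = descriptive_compare(df, np.array(labels), "diabetes",
                                  kind="categorical")
        assert res.p_value < 0.001

    def test_identical_distributions_p_near_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0] * 10})
        labels = np.array(([0] * 4 + [1] * 4) * 5)
        res = descriptive_compare(df, labels, "x", kind="continuous")
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_two_group_anova_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.7, 1, 30)])
        labels = np.repeat([0, 1], 30)
        df = pd.DataFrame({"x": x})
        res = descriptive_compare(df, labels, "x", kind="continuous")
        t_p = stats.ttest_ind(x[:30], x[30:], equal_var=True).pvalue
        assert res.p_value == pytest.approx(t_p, rel=1e-9)

    def test_constant_variable_undefined(self):
        df = pd.DataFrame({"x": [5.0] * 20})
        res = descriptive_compare(df, np.repeat([0, 1], 10), "x",
                                  kind="continuous")
        assert np.isnan(res.p_value)
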