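"""Normality-routed comparisons, contingency tests, regression, ROC."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from artix.stats import (
    anova_bonferroni,
    chi_square_2x2,
    cohort_report,
    compare_groups,
    correlate,
    fit_regression,
    kruskal_dunn,
    mcnemar,
    roc_analysis,
    variance_inflation_factors,
)
from artix.types import CollinearityError


def chi2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestCompareGroups:
    def test_identical_samples_route_to_t_with_p_one(self):
        x = np.random.default_rng(0).normal(size=30)
        res = compare_groups(x, x.copy())
        assert res.test_name == "t"
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_lognormal_sample_routes_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = np.exp(rng.normal(size=50))  # heavily skewed
        res = compare_groups(x, y)
        assert res.test_name == "MannWhitney"
        assert "rejected" in res.routing_reason

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(11)
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert res.p_value < 0.001

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_reference_thermography_tables(self):
        # returned/not-returned by group, global and September-December
        _, p_global = chi_square_2x2([[17, 28], [15, 7]])
        _, p_sepdec = chi_square_2x2([[6, 16], [8, 4]])
        assert round(p_global, 2) == 0.02
        assert round(p_sepdec, 2) == 0.03

    def test_independent_table_gives_zero_statistic(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_perfect_association(self):
        stat, p = chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_matches_closed_form(self, counts):
        a, b, c, d = counts
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        assert stat == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-9)


class TestMcNemar:
    def test_balanced_discordance(self):
        a = [True] * 10 + [False] * 10
        b = [False] * 10 + [True] * 10
        assert mcnemar(a, b) == pytest.approx(1.0)

    def test_nine_versus_one(self):
        a = [True] * 9 + [False]
        b = [False] * 9 + [True]
        assert mcnemar(a, b) == pytest.approx(2 * (1 + 10) / 2 ** 10)

    def test_no_discordance_warns(self):
        with pytest.warns(RuntimeWarning):
            assert mcnemar([True, False], [True, False]) == 1.0


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, x, "pearson")[0] == pytest.approx(1.0)
        assert correlate(x, x, "spearman")[0] == pytest.approx(1.0)

    def test_monotone_nonlinear_separates_methods(self):
        x = np.arange(1.0, 20.0)
        rs, _ = correlate(x, x ** 3, "spearman")
        rp, _ = correlate(x, x ** 3, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(17)
        r, _ = correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0] * 10, np.arange(10.0))


class TestRegression:
    def test_orthogonal_predictors_have_unit_vif(self):
        x = pd.DataFrame({"a": [1, 1, 1, 1, -1, -1, -1, -1.0],
                          "b": [1, 1, -1, -1, 1, 1, -1, -1.0]})
        vifs = variance_inflation_factors(x)
        assert vifs["a"] == pytest.approx(1.0)
        assert vifs["b"] == pytest.approx(1.0)

    def test_duplicate_predictor_raises_naming_offenders(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        with pytest.raises(CollinearityError) as exc:
            fit_regression(rng.normal(size=30), pd.DataFrame({"a": x, "b": x}))
        assert set(exc.value.offenders) == {"a", "b"}

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=200)
        y = 10 + 14 * x1 + rng.normal(0, 1, 200)
        res = fit_regression(y, pd.DataFrame({"x1": x1}))
        assert 12 <= res.coefficients["x1"] <= 16
        assert res.p_values["x1"] < 1e-6

    def test_high_vif_predictor_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        near_copy = x + rng.normal(0, 0.01, 100)  # VIF >> 10, not perfect
        res = fit_regression(2 * x + rng.normal(0, 1, 100),
                             pd.DataFrame({"x": x, "near_copy": near_copy}))
        assert res.dropped  # at least one flagged
        assert all(v <= 10 for v in res.vif.values())


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([300.0] * 5 + [400.0] * 5, ["RP"] * 5 + ["HC"] * 5)
        assert res.auc == 1.0
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0
        assert (res.tp, res.tn, res.fp, res.fn) == (5, 5, 0, 0)

    def test_orientation_flag(self):
        scores, labels = [1, 2, 3, 4], ["RP", "RP", "HC", "HC"]
        assert roc_analysis(scores, labels, direction="lower").auc == 1.0
        assert roc_analysis(scores, labels, direction="higher").auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["RP", "RP"])

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0, 1, 40), rng.normal(1, 1, 60)]
        labels = np.array(["RP"] * 40 + ["HC"] * 60)
        res = roc_analysis(scores, labels, direction="lower")
        assert res.ci95_low <= res.auc <= res.ci95_high
        assert 0.0 <= res.ci95_low and res.ci95_high <= 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_auc_equals_mann_whitney_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.5, 1, 12)
        neg = rng.normal(0, 1, 15)
        res = roc_analysis(np.r_[pos, neg], np.array(["RP"] * 12 + ["HC"] * 15),
                           direction="higher")
        u = mannwhitneyu(pos, neg).statistic
        assert res.auc == pytest.approx(u / (12 * 15), abs=1e-9)


class TestMultiGroupUtilities:
    def test_anova_detects_shifted_group(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                  "c": rng.normal(2, 1, 30)}
        out = anova_bonferroni(groups)
        assert out["p_value"] < 0.001
        assert out["posthoc"]["a|c"] < 0.01
        assert out["posthoc"]["a|b"] > 0.05

    def test_kruskal_detects_shifted_group(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                  "c": rng.normal(2, 1, 30)}
        out = kruskal_dunn(groups)
        assert out["p_value"] < 0.001
        assert out["posthoc"]["a|c"] < 0.01


class TestCohortReport:
    def test_seven_roc_rows(self, fast_cohort):
        _, sessions, _ = fast_cohort
        report = cohort_report(sessions)
        rocs = [tp["roc"] for tp in report.strata["global"]["timepoints"].values()
                if "roc" in tp]
        assert len(rocs) == 7

    def test_report_is_deterministic(self, fast_cohort):
        _, sessions, _ = fast_cohort
        a = cohort_report(sessions).to_json()
        b = cohort_report(sessions).to_json()
        assert a == b
        json.loads(a)  # valid JSON

    def test_single_group_cohort_skipped_with_warning(self, fast_cohort):
        _, sessions, _ = fast_cohort
        rp_only = [s for s in sessions if s.group == "RP"]
        with pytest.warns(RuntimeWarning, match="lacks a group"):
            report = cohort_report(rp_only)
        assert report.strata == {} and report.pooled == {}

    def test_pooled_blocks_label_both_conventions(self, fast_cohort):
        _, sessions, _ = fast_cohort
        report = cohort_report(sessions)
        for measure in ("artix", "thermal"):
            assert {"all_assessments", "per_subject_means"} <= set(report.pooled[measure])
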