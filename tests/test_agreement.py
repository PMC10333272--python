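"""Concordance, Bland-Altman, paired tests and the exact Wilcoxon null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from slice3bc import (lin_ccc, ccc_confidence_interval, bland_altman,
                      paired_t, wilcoxon_signed_rank, agreement_report,
                      subgroup_concordance, sensitivity_report,
                      CohortSpec, make_cohort, make_longitudinal,
                      fit_ols, PUBLISHED_AT)
from slice3bc.agreement import bland_altman_points, bmi_class
from slice3bc.prediction import AT_PREDICTORS


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert lin_ccc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_examples(self):
        # population moments: ccc((1,2,3),(1,2,4)) = 6/7; shift case = 4/7
        assert lin_ccc([1, 2, 3], [1, 2, 4]) == pytest.approx(6 / 7, abs=1e-12)
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lin_ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_symmetry(self):
        x = [1.0, 2.0, 3.5, 7.0]
        y = [1.1, 2.4, 3.1, 6.2]
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x), abs=1e-14)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=30))
    def test_bounded_by_pearson(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.std() < 1e-6 or y.std() < 1e-6:
            return
        ccc = lin_ccc(x, y)
        r = stats.pearsonr(x, y).statistic
        assert abs(ccc) <= abs(r) + 1e-9
        assert -1.0 - 1e-12 <= ccc <= 1.0 + 1e-12

    def test_joint_rescaling_invariance_but_single_rescaling_penalty(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([1.2, 1.9, 4.4, 7.6])
        base = lin_ccc(x, y)
        assert lin_ccc(3.0 * x + 2.0, 3.0 * y + 2.0) == pytest.approx(base, abs=1e-12)
        assert lin_ccc(x, 3.0 * y + 2.0) < base


class TestCCCInterval:
    def test_reference_interval_reproduced(self):
        # agreement to the printed 3 decimals (the published estimate 0.986
        # is itself rounded)
        ci = ccc_confidence_interval(0.986, 310)
        assert ci.low == pytest.approx(0.982, abs=1e-3)
        assert ci.high == pytest.approx(0.989, abs=1e-3)

    def test_interval_shrinks_with_n(self):
        w10 = ccc_confidence_interval(0.5, 10)
        w100 = ccc_confidence_interval(0.5, 100)
        assert (w100.high - w100.low) < (w10.high - w10.low)
        w100000 = ccc_confidence_interval(0.5, 100_000)
        assert (w100000.high - w100000.low) < 0.02

    def test_interval_contains_estimate(self):
        ci = ccc_confidence_interval(0.7, 50)
        assert ci.low < 0.7 < ci.high

    def test_degenerate_flagged(self):
        ci = ccc_confidence_interval(1.0, 50)
        assert ci.degenerate and ci.low == ci.high == 1.0


class TestBlandAltman:
    def test_identity_zero_bias_zero_loa(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        bias, sd, lo, hi = bland_altman(x, x)
        assert bias == 0.0 and sd == 0.0 and lo == 0.0 and hi == 0.0

    def test_pure_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, sd, lo, hi = bland_altman(x, x + 1.0)
        assert bias == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_fitted_vs_observed_bias_exactly_zero(self, default_cohort):
        model = fit_ols(default_cohort, "measured_total_at", AT_PREDICTORS)
        bias, sd, lo, hi = bland_altman(
            default_cohort["measured_total_at"].to_numpy(), model.fitted)
        assert bias == pytest.approx(0.0, abs=1e-9)
        assert lo <= bias <= hi

    def test_reference_cohort_loa_halfwidth_matches_random_error(self, default_cohort):
        # residual SD 2.18 kg -> LoA half-width ~ 1.96 * 2.18 = 4.3 kg
        pred = PUBLISHED_AT.predict_frame(default_cohort)
        bias, sd, lo, hi = bland_altman(
            default_cohort["measured_total_at"].to_numpy(), pred.to_numpy())
        assert abs(bias) < 0.5
        assert (hi - lo) / 2 == pytest.approx(4.3, abs=0.5)

    def test_scatter_points_schema(self):
        pts = bland_altman_points([1.0, 2.0], [2.0, 2.0])
        assert list(pts.columns) == ["mean", "difference"]
        assert pts["mean"].tolist() == [1.5, 2.0]


class TestPairedT:
    def test_identical_series_degenerate(self):
        p, degenerate = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and degenerate

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = x + rng.normal(size=30)
            p, _ = paired_t(x, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(22)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=79)
            y = x + 1.0 + rng.normal(size=79)
            p, _ = paired_t(x, y)
            rejections += p < 0.05
        assert rejections / reps > 0.99


class TestWilcoxon:
    @staticmethod
    def _enumeration_oracle(d):
        """Exact two-sided p by brute force over all 2^n sign assignments."""
        d = np.asarray(d, float)
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = d.size
        ws = []
        for signs in itertools.product([0, 1], repeat=n):
            ws.append(sum(r for s, r in zip(signs, ranks) if s))
        ws = np.array(ws)
        p_le = np.mean(ws <= w_obs + 1e-9)
        p_ge = np.mean(ws >= w_obs - 1e-9)
        return min(1.0, 2 * min(p_le, p_ge))

    def test_symmetric_differences_p_one(self):
        p, _ = wilcoxon_signed_rank([1, -1, 2, -2, 3, -3])
        assert p == pytest.approx(1.0)

    def test_all_positive_n6_exact(self):
        p, _ = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert p == pytest.approx(2 / 64, abs=1e-12)

    def test_all_zero_degenerate(self):
        p, degenerate = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0 and degenerate

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(4, 11))
            d = np.round(rng.normal(size=n), 1)  # rounding forces ties
            d = d[d != 0]
            if d.size < 2:
                continue
            p_impl, _ = wilcoxon_signed_rank(d)
            assert p_impl == pytest.approx(self._enumeration_oracle(d),
                                           abs=1e-12), d

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            d = rng.normal(size=12)
            p_impl, _ = wilcoxon_signed_rank(d)
            p_scipy = stats.wilcoxon(d, method="exact").pvalue
            assert p_impl == pytest.approx(p_scipy, abs=1e-9)

    def test_large_n_null_rejection_rate(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            p, _ = wilcoxon_signed_rank(rng.normal(size=100))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestSubgroups:
    def test_sex_partition_sums_to_total(self, default_cohort):
        table = default_cohort.copy()
        table["_pred"] = PUBLISHED_AT.predict_frame(table)
        reports = subgroup_concordance(table, "measured_total_at", "_pred",
                                       grouping="sex")
        assert sum(r.n for r in reports) == len(table)
        assert {r.label for r in reports} == {"men", "women"}

    def test_bmi_partition(self, default_cohort):
        table = default_cohort.copy()
        table["_pred"] = PUBLISHED_AT.predict_frame(table)
        reports = subgroup_concordance(table, "measured_total_at", "_pred",
                                       grouping="bmi_class")
        assert sum(r.n for r in reports) == len(table)
        for r in reports:
            assert -1.0 <= r.ccc <= 1.0

    def test_small_subgroup_flagged_wide_ci(self):
        table = make_cohort(CohortSpec(n=14), seed=9)
        table["_pred"] = PUBLISHED_AT.predict_frame(table)
        report = agreement_report(table["measured_total_at"], table["_pred"])
        assert report.wide_ci

    def test_single_group_equals_unpartitioned(self, default_cohort):
        table = default_cohort.copy()
        table["_pred"] = PUBLISHED_AT.predict_frame(table)
        table["sex_code"] = 0
        grouped = subgroup_concordance(table, "measured_total_at", "_pred",
                                       grouping="sex")
        overall = agreement_report(table["measured_total_at"], table["_pred"])
        assert len(grouped) == 1
        assert grouped[0].ccc == pytest.approx(overall.ccc, abs=1e-12)
        assert grouped[0].bias == pytest.approx(overall.bias, abs=1e-12)

    def test_bmi_class_boundaries(self):
        assert bmi_class(70.0, 1.75) == "normal"       # 22.9
        assert bmi_class(85.0, 1.75) == "overweight"   # 27.8
        assert bmi_class(100.0, 1.75) == "obese"       # 32.7


class TestSensitivity:
    def test_longitudinal_methods_concordant_when_change_is_shared(self):
        cohort = make_cohort(CohortSpec(n=79), seed=10)
        paired = make_longitudinal(cohort, -2.0, 1.0, 0.5, 1.0, seed=11)
        t0 = paired.rename(columns=lambda c: c.removesuffix("_t0")
                           if c.endswith("_t0") else c)
        t2 = paired.rename(columns=lambda c: c.removesuffix("_t2")
                           if c.endswith("_t2") else c)
        t0["weight"] = paired["weight_t0"]
        t2["weight"] = paired["weight_t2"]
        pred_t0 = PUBLISHED_AT.predict_frame(t0)
        pred_t2 = PUBLISHED_AT.predict_frame(t2)
        report = sensitivity_report(paired["measured_total_at_t0"],
                                    paired["measured_total_at_t2"],
                                    pred_t0, pred_t2, tissue="AT")
        assert report.n == 79
        assert report.delta_measured_mean == pytest.approx(-2.0, abs=0.5)
        # both methods register the same average change (the proportional
        # co-shift keeps predictions approximately, not exactly, unbiased)
        assert abs(report.delta_measured_mean - report.delta_predicted_mean) < 0.75
        assert 0.0 <= report.wilcoxon_p_between <= 1.0
        # both methods individually detect the injected loss
        assert report.wilcoxon_p_measured < 0.001
        assert report.wilcoxon_p_predicted < 0.001

    def test_identical_methods_p_one(self):
        x0 = np.array([30.0, 31.0, 32.0, 33.0, 34.0, 36.0])
        x2 = x0 - 1.0
        report = sensitivity_report(x0, x2, x0, x2)
        assert report.wilcoxon_p_between == 1.0
        assert report.delta_gap_mean == 0.0
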