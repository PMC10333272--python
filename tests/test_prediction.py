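"""Published equations, OLS refitting, stepwise AIC, influence, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from slice3bc import (SubjectRecord, PUBLISHED_AT, PUBLISHED_ATFM,
                      EQUATION_VARIANTS, predict_total_at, predict_total_atfm,
                      fit_ols, select_stepwise_aic, select_best_aic,
                      cooks_filter, cooks_distances, residual_diagnostics,
                      CohortSpec, make_cohort)
from slice3bc.prediction import AT_PREDICTORS, ATFM_PREDICTORS, aic_gaussian


def _subject(**kw):
    base = dict(id="s", age=50.0, sex_code=0, height=1.75, weight=90.0,
                at_t67=0.2, at_l45=0.4, at_thigh=0.2,
                atfm_t67=0.6, atfm_l45=0.3, atfm_thigh=0.35)
    base.update(kw)
    return SubjectRecord(**base)


class TestPublishedEquations:
    def test_population_mean_covariates_reproduce_printed_means(self):
        means = dict(age=50.8, sex_code=70 / 310, weight=93.0, height=1.72,
                     at_t67=0.20, at_l45=0.43, at_thigh=0.17,
                     atfm_t67=0.65, atfm_l45=0.33, atfm_thigh=0.36)
        assert predict_total_at(means) == pytest.approx(32.38, abs=0.3)
        assert predict_total_atfm(means) == pytest.approx(62.26, abs=0.3)

    def test_intercept_at_zero_covariates(self):
        zeros = dict(age=0, sex_code=0, weight=0, height=0,
                     at_t67=0, at_l45=0, at_thigh=0,
                     atfm_t67=0, atfm_l45=0, atfm_thigh=0)
        assert predict_total_at(zeros) == pytest.approx(-12.74105)
        assert predict_total_atfm(zeros) == pytest.approx(-33.10721)

    def test_sex_coefficient_additivity(self):
        male = _subject(sex_code=0)
        female = _subject(sex_code=1)
        assert (predict_total_at(female.as_dict()) - predict_total_at(male.as_dict())
                ) == pytest.approx(4.27634, abs=1e-10)
        assert (predict_total_atfm(female.as_dict()) - predict_total_atfm(male.as_dict())
                ) == pytest.approx(-3.58052, abs=1e-10)

    def test_affine_in_covariates(self):
        a = dict(age=40.0, sex_code=0, weight=80.0, height=1.70,
                 at_t67=0.1, at_l45=0.3, at_thigh=0.1,
                 atfm_t67=0.5, atfm_l45=0.3, atfm_thigh=0.3)
        b = dict(age=60.0, sex_code=1, weight=110.0, height=1.80,
                 at_t67=0.3, at_l45=0.6, at_thigh=0.3,
                 atfm_t67=0.7, atfm_l45=0.4, atfm_thigh=0.4)
        lam = 0.3
        mix = {k: lam * a[k] + (1 - lam) * b[k] for k in a}
        assert predict_total_at(mix) == pytest.approx(
            lam * predict_total_at(a) + (1 - lam) * predict_total_at(b), abs=1e-10)

    def test_missing_field_named(self):
        with pytest.raises(KeyError, match="weight"):
            PUBLISHED_AT.predict({"age": 50, "sex_code": 0, "at_t67": 0.2,
                                  "at_l45": 0.4, "at_thigh": 0.2})

    def test_table_variant_differs_and_is_tagged(self):
        at_txt = EQUATION_VARIANTS["text-v1"]["TOTAL_AT"]
        at_tab = EQUATION_VARIANTS["table-v1"]["TOTAL_AT"]
        assert at_txt.version == "text-v1" and at_tab.version == "table-v1"
        assert at_txt.coefficients["sex_code"] != at_tab.coefficients["sex_code"]

    def test_subject_record_validation(self):
        with pytest.raises(ValueError, match="sex_code"):
            _subject(sex_code=2)
        with pytest.raises(ValueError, match="height"):
            _subject(height=175.0)
        with pytest.raises(ValueError, match="at_l45"):
            _subject(at_l45=-0.1)


class TestFitOLS:
    def test_noise_free_table_recovers_coefficients_exactly(self):
        spec = CohortSpec(n=80, residual_sd_at=0.0, residual_sd_atfm=0.0)
        table = make_cohort(spec, seed=1)
        model = fit_ols(table, "measured_total_at", AT_PREDICTORS)
        assert model.intercept == pytest.approx(PUBLISHED_AT.intercept, rel=1e-6)
        for name, coef in PUBLISHED_AT.coefficients.items():
            assert model.coefficients[name] == pytest.approx(coef, rel=1e-6), name
        assert model.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_coefficient_recovery_within_2se_coverage(self):
        # nominal 95.4% coverage of the +/-2 SE band; assert joint coverage
        # across seeds and coefficients stays above 90%
        hits = total = 0
        for seed in range(50):
            table = make_cohort(CohortSpec(), seed=seed)
            model = fit_ols(table, "measured_total_at", AT_PREDICTORS)
            se = model._sm_result.bse
            for name, true_coef in PUBLISHED_AT.coefficients.items():
                total += 1
                hits += abs(model.coefficients[name] - true_coef) <= 2 * se[name]
        assert hits / total >= 0.90

    def test_fitted_mean_equals_response_mean(self, default_cohort):
        model = fit_ols(default_cohort, "measured_total_at", AT_PREDICTORS)
        assert model.fitted.mean() == pytest.approx(
            default_cohort["measured_total_at"].mean(), abs=1e-9)

    def test_see_definition(self, default_cohort):
        model = fit_ols(default_cohort, "measured_total_atfm", ATFM_PREDICTORS)
        rss = float(model.residuals @ model.residuals)
        p1 = len(ATFM_PREDICTORS) + 1
        assert model.see == pytest.approx(np.sqrt(rss / (model.n - p1)))
        # residual SD should track the generative 2.69 kg
        assert model.see == pytest.approx(2.69, abs=0.45)

    def test_duplicated_predictor_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="duplicat"):
            fit_ols(default_cohort, "measured_total_at",
                    ["age", "weight", "age"])

    def test_collinear_design_names_columns(self, default_cohort):
        table = default_cohort.copy()
        table["weight_twice"] = 2.0 * table["weight"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(table, "measured_total_at",
                    ["age", "weight", "weight_twice"])

    def test_aic_ordering_invariant_to_mean_shift(self, default_cohort):
        shifted = default_cohort.copy()
        shifted["measured_total_at"] += 100.0
        m1 = fit_ols(default_cohort, "measured_total_at", AT_PREDICTORS)
        m2 = fit_ols(default_cohort, "measured_total_at", AT_PREDICTORS[:4])
        s1 = fit_ols(shifted, "measured_total_at", AT_PREDICTORS)
        s2 = fit_ols(shifted, "measured_total_at", AT_PREDICTORS[:4])
        assert (m1.aic < m2.aic) == (s1.aic < s2.aic)
        assert m1.aic == pytest.approx(s1.aic, abs=1e-6)

    def test_adjusted_r2_concentrates_at_calibrated_level(self, default_cohort):
        # with residual SD 2.18 and response SD ~12-13, adjusted R2 ~ 0.97
        model = fit_ols(default_cohort, "measured_total_at", AT_PREDICTORS)
        sd = default_cohort["measured_total_at"].std(ddof=1)
        expected = 1.0 - (2.18 / sd) ** 2
        assert model.adjusted_r2 == pytest.approx(expected, abs=0.01)


class TestStepwiseAIC:
    def _table_with_noise_column(self, seed):
        table = make_cohort(CohortSpec(), seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        table["pure_noise"] = rng.normal(size=len(table))
        return table

    def test_noise_candidate_mostly_excluded_and_signal_always_kept(self):
        excluded = 0
        runs = 100
        for seed in range(runs):
            table = self._table_with_noise_column(seed)
            model = select_stepwise_aic(
                table, "measured_total_at",
                list(AT_PREDICTORS) + ["pure_noise"], direction="both")
            kept = set(model.retained_predictors)
            assert {"weight", "at_t67", "at_l45", "at_thigh"} <= kept
            excluded += "pure_noise" not in kept
        # AIC retains a pure-noise term with prob ~ P(chi2_1 > 2) ~ 0.16
        assert excluded / runs >= 0.70

    def test_height_dropped_from_adipose_model(self):
        # the generative AT equation has no height term; selection should
        # usually drop height, the development cohort's own finding
        dropped = 0
        runs = 50
        for seed in range(runs):
            table = make_cohort(CohortSpec(), seed=seed)
            model = select_stepwise_aic(
                table, "measured_total_at",
                ["age", "sex_code", "height", "weight",
                 "at_t67", "at_l45", "at_thigh"], direction="both")
            dropped += "height" not in model.retained_predictors
        assert dropped / runs >= 0.70

    def test_forward_backward_agree_on_strong_signal(self, default_cohort):
        fwd = select_stepwise_aic(default_cohort, "measured_total_at",
                                  AT_PREDICTORS, "forward")
        bwd = select_stepwise_aic(default_cohort, "measured_total_at",
                                  AT_PREDICTORS, "backward")
        assert set(fwd.retained_predictors) == set(bwd.retained_predictors)

    def test_best_of_three_directions_flagged(self, default_cohort):
        best, models = select_best_aic(default_cohort, "measured_total_at",
                                       AT_PREDICTORS)
        assert best.aic == min(m.aic for m in models.values())
        assert best.search_path  # path recorded

    def test_empty_candidates_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="empty"):
            select_stepwise_aic(default_cohort, "measured_total_at", [])


class TestCooksFilter:
    def test_gross_outlier_has_max_distance_and_is_removed(self):
        table = make_cohort(CohortSpec(n=100), seed=2)
        table.loc[13, "measured_total_at"] += 10 * 2.18
        dists = cooks_distances(table, "measured_total_at", AT_PREDICTORS)
        assert dists.idxmax() == 13
        kept, removed, _ = cooks_filter(table, "measured_total_at",
                                        AT_PREDICTORS, threshold_rule="4/n")
        assert 13 in removed
        assert 13 not in kept.index

    def test_clean_table_zero_removals_under_conservative_rule(self):
        removals = 0
        for seed in range(50):
            table = make_cohort(CohortSpec(), seed=seed)
            _, removed, _ = cooks_filter(table, "measured_total_at",
                                         AT_PREDICTORS, threshold_rule=1.0)
            removals += len(removed) > 0
        assert removals / 50 <= 0.10

    def test_small_table_distances_finite(self):
        table = make_cohort(CohortSpec(n=5), seed=3)
        dists = cooks_distances(table, "measured_total_at", ["weight"])
        assert np.isfinite(dists).all()

    def test_excessive_removal_aborts(self):
        table = make_cohort(CohortSpec(n=60), seed=4)
        with pytest.raises(RuntimeError, match="aborting"):
            cooks_filter(table, "measured_total_at", AT_PREDICTORS,
                         threshold_rule=1e-8)


class TestDiagnostics:
    def test_null_gaussian_residuals_centre_dw_at_2(self):
        rng = np.random.default_rng(42)
        inside = 0
        runs = 200
        dws = []
        for _ in range(runs):
            report = residual_diagnostics(rng.normal(size=310))
            dws.append(report.durbin_watson)
            inside += 1.8 < report.durbin_watson < 2.2
        # SD(DW) ~ 2/sqrt(n) = 0.11, so +/-0.2 covers ~92% of the null
        assert inside / runs >= 0.85
        assert np.mean(dws) == pytest.approx(2.0, abs=0.03)

    def test_ar1_residuals_flagged_dependent(self):
        rng = np.random.default_rng(7)
        e = np.empty(310)
        e[0] = rng.normal()
        for t in range(1, 310):
            e[t] = 0.8 * e[t - 1] + rng.normal()
        report = residual_diagnostics(e)
        assert report.durbin_watson < 1.5
        assert not report.flags["independence"]

    def test_heteroscedastic_residuals_fail_bartlett(self):
        rng = np.random.default_rng(11)
        rejections = 0
        runs = 50
        for _ in range(runs):
            fitted = np.sort(rng.normal(size=310))
            scale = np.where(fitted < np.quantile(fitted, 1 / 3), 1.0,
                             np.where(fitted < np.quantile(fitted, 2 / 3), 1.5, 2.0))
            resid = rng.normal(size=310) * scale
            report = residual_diagnostics(resid, fitted=fitted)
            rejections += report.bartlett_p < 0.05
        assert rejections / runs >= 0.90

    def test_small_n_suppressed_with_notice(self):
        report = residual_diagnostics(np.arange(5.0))
        assert report.suppressed
        assert "suppressed" in report.notice
        assert report.flags == {}
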