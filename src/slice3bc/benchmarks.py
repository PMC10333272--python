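"""Self-consistency benchmarks of the prediction method.

These routines recompute, from scratch, the headline quantities of the
three-slice method under its documented study conditions:

* the mean predicted whole-body AT/ATFM at the development cohort's
  covariate means (sex entered as the cohort female fraction), and
* the adjusted R² and predicted-vs-measured concordance of models refit on
  synthetic cohorts calibrated so that the published equations' linear
  predictors have the dispersion implied by the printed response SDs and
  standard errors of estimate.

They are shared by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import lin_ccc
from .phantom import (CohortSpec, calibrate_slice_sds, make_cohort,
                      REFERENCE_COHORT_COVARIATES, REFERENCE_FEMALE_FRACTION,
                      REFERENCE_SEE_AT, REFERENCE_SEE_ATFM,
                      REFERENCE_MEASURED_SD_AT, REFERENCE_MEASURED_SD_ATFM)
from .prediction import (predict_total_at, predict_total_atfm,
                         fit_ols, AT_PREDICTORS, ATFM_PREDICTORS)


def reference_mean_covariates() -> dict[str, float]:
    """Development-cohort covariate means, with sex as the female fraction."""
    means = {name: cov.mean for name, cov in REFERENCE_COHORT_COVARIATES.items()}
    means["sex_code"] = REFERENCE_FEMALE_FRACTION
    return means


def mean_predicted_at() -> float:
    """Published AT equation at the cohort covariate means (kg)."""
    return predict_total_at(reference_mean_covariates())


def mean_predicted_atfm() -> float:
    """Published ATFM equation at the cohort covariate means (kg)."""
    return predict_total_atfm(reference_mean_covariates())


def target_predictor_sd(tissue: str) -> float:
    """Linear-predictor SD implied by printed response SD and SEE (kg)."""
    if tissue == "AT":
        return float(np.sqrt(REFERENCE_MEASURED_SD_AT**2 - REFERENCE_SEE_AT**2))
    if tissue == "ATFM":
        return float(np.sqrt(REFERENCE_MEASURED_SD_ATFM**2 - REFERENCE_SEE_ATFM**2))
    raise ValueError("tissue must be 'AT' or 'ATFM'")


@dataclass
class RefitSummary:
    """Monte-Carlo summary of refit models on calibrated synthetic cohorts."""

    tissue: str
    n_subjects: int
    n_seeds: int
    adjusted_r2_pct_mean: float
    adjusted_r2_pct_sd: float
    ccc_mean: float
    ccc_sd: float
    see_mean: float


def refit_benchmark(tissue: str, seed: int, n_seeds: int = 20,
                    n_subjects: int = 310) -> RefitSummary:
    """Generate calibrated cohorts, refit OLS, summarise fit and concordance.

    For each of ``n_seeds`` independent cohorts of ``n_subjects``, measured
    totals are the published equation plus Gaussian noise at the printed
    SEE; the model is refit on the equation's own predictors and the
    adjusted R² and the concordance between refit predictions and measured
    values are recorded.
    """
    if tissue == "AT":
        response, predictors = "measured_total_at", AT_PREDICTORS
    elif tissue == "ATFM":
        response, predictors = "measured_total_atfm", ATFM_PREDICTORS
    else:
        raise ValueError("tissue must be 'AT' or 'ATFM'")

    root = np.random.SeedSequence(seed)
    cal_seed, *cohort_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                               for s in root.spawn(n_seeds + 1)]
    spec = calibrate_slice_sds(CohortSpec(n=n_subjects), tissue,
                               target_predictor_sd(tissue), seed=cal_seed)
    r2, ccc, see = [], [], []
    for s in cohort_seeds:
        table = make_cohort(spec, seed=s)
        model = fit_ols(table, response, predictors)
        r2.append(100.0 * model.adjusted_r2)
        ccc.append(lin_ccc(table[response].to_numpy(), model.fitted))
        see.append(model.see)
    return RefitSummary(
        tissue=tissue, n_subjects=n_subjects, n_seeds=n_seeds,
        adjusted_r2_pct_mean=float(np.mean(r2)),
        adjusted_r2_pct_sd=float(np.std(r2, ddof=1)),
        ccc_mean=float(np.mean(ccc)), ccc_sd=float(np.std(ccc, ddof=1)),
        see_mean=float(np.mean(see)))
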