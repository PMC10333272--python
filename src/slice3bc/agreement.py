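"""Concordance and agreement between predicted and measured body composition.

Implements the validation statistics of the three-slice method: Lin's
concordance correlation coefficient (CCC) with a Fisher-z confidence
interval, Bland-Altman bias and 95% limits of agreement, paired t-tests,
an exact Wilcoxon signed-rank test for longitudinal sensitivity, and
subgroup reports by sex and BMI class.

Lin's CCC uses population (1/n) moments, its original definition:

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

It equals the Pearson correlation scaled down by any mean or variance
mismatch, so it penalises both scatter and systematic shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Subgroups with fewer pairs than this get a wide-confidence-interval flag.
WIDE_CI_N = 15


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("degenerate input: both series constant with equal means")
    return float(2.0 * sxy / denom)


@dataclass(frozen=True)
class ConfidenceInterval:
    low: float
    high: float
    degenerate: bool = False


def ccc_confidence_interval(ccc: float, n: int,
                            alpha: float = 0.05) -> ConfidenceInterval:
    """Fisher z-transform normal-approximation CI for a CCC.

    ``ccc = ±1`` returns a degenerate zero-width interval with a flag.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher-z interval")
    if abs(ccc) >= 1.0:
        return ConfidenceInterval(low=ccc, high=ccc, degenerate=True)
    z = np.arctanh(ccc)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    return ConfidenceInterval(low=float(np.tanh(z - crit * se)),
                              high=float(np.tanh(z + crit * se)))


@dataclass
class AgreementReport:
    """Bias, limits of agreement and concordance for one set of pairs.

    ``bias`` is the mean of predicted − measured; ``loa_low``/``loa_high``
    are ``bias ± 1.96 × SD`` of the differences (sample SD).  ``wide_ci``
    flags subgroups too small for a stable CCC interval.
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    paired_t_p: float
    label: str = "all"
    wide_ci: bool = False
    degenerate_t: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label", "n", "bias", "sd_diff", "loa_low", "loa_high",
            "ccc", "ccc_ci_low", "ccc_ci_high", "paired_t_p", "wide_ci")}


def bland_altman(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float, float, float]:
    """Bland-Altman bias and 95% limits of agreement of y − x.

    Returns ``(bias, sd_diff, loa_low, loa_high)`` with the 1.96 multiplier
    and the sample (n−1) SD of the paired differences.
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman_points(x: Sequence[float], y: Sequence[float]) -> pd.DataFrame:
    """Scatter data for an external Bland-Altman plot: pair means vs
    differences (y − x)."""
    x, y = _paired(x, y)
    return pd.DataFrame({"mean": (x + y) / 2.0, "difference": y - x})


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, bool]:
    """Two-sided paired t-test p-value for mean difference zero.

    Zero-variance differences are degenerate: returns ``(1.0, True)``.
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    if float(d.std(ddof=1)) == 0.0:
        return 1.0, True
    t = stats.ttest_rel(y, x)
    return float(t.pvalue), False


def _exact_signed_rank_p(ranks2: np.ndarray, w2_plus: float) -> float:
    """Exact two-sided p over the 2^n equiprobable sign assignments.

    ``ranks2`` are doubled mid-ranks (integers); the null distribution of
    the doubled positive-rank sum is built by polynomial convolution.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = (dist + shifted) / 2.0
    w = int(round(w2_plus))
    p_le = float(dist[:w + 1].sum())
    p_ge = float(dist[w:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(differences: Sequence[float],
                         exact_threshold: int = 25) -> tuple[float, bool]:
    """Wilcoxon signed-rank test of symmetry about zero.

    Zeros are dropped (Wilcoxon's original treatment) and ties mid-ranked.
    With at most ``exact_threshold`` non-zero differences the p-value is
    exact (full 2^n sign-assignment null, tie-aware); above, a normal
    approximation with continuity and tie corrections is used.  All-zero
    input is degenerate: returns ``(1.0, True)``.

    Returns ``(two-sided p, degenerate flag)``.
    """
    d = np.asarray(differences, float)
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        ranks2 = np.round(2.0 * ranks).astype(int)
        return _exact_signed_rank_p(ranks2, 2.0 * w_plus), False
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var == 0:
        return 1.0, True
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(z)), False


def agreement_report(measured: Sequence[float], predicted: Sequence[float],
                     label: str = "all", alpha: float = 0.05) -> AgreementReport:
    """Full agreement report for one group of measured/predicted pairs."""
    x, y = _paired(measured, predicted)
    bias, sd, lo, hi = bland_altman(x, y)
    ccc = lin_ccc(x, y)
    ci = ccc_confidence_interval(ccc, max(x.size, 4), alpha=alpha)
    p, degenerate = paired_t(x, y) if x.size >= 3 else (1.0, True)
    return AgreementReport(n=int(x.size), bias=bias, sd_diff=sd,
                           loa_low=lo, loa_high=hi, ccc=ccc,
                           ccc_ci_low=ci.low, ccc_ci_high=ci.high,
                           paired_t_p=p, label=label,
                           wide_ci=x.size < WIDE_CI_N, degenerate_t=degenerate)


def bmi_class(weight_kg: float, height_m: float) -> str:
    """WHO-style class from BMI: ``normal`` (<25), ``overweight`` (25–30),
    ``obese`` (>30)."""
    bmi = weight_kg / height_m**2
    if bmi < 25.0:
        return "normal"
    if bmi <= 30.0:
        return "overweight"
    return "obese"


def subgroup_concordance(table: pd.DataFrame, measured_col: str,
                         predicted_col: str, grouping: str = "sex",
                         alpha: float = 0.05) -> list[AgreementReport]:
    """Agreement reports per subgroup (``sex`` or ``bmi_class``).

    ``sex`` uses the 0/1 ``sex_code`` column; ``bmi_class`` derives the
    class from weight and height.  Empty subgroups are skipped.
    """
    if grouping == "sex":
        keys = table["sex_code"].map({0: "men", 1: "women"})
    elif grouping == "bmi_class":
        keys = pd.Series([bmi_class(w, h) for w, h in
                          zip(table["weight"], table["height"])],
                         index=table.index)
    else:
        raise ValueError("grouping must be 'sex' or 'bmi_class'")
    reports = []
    for name, idx in table.groupby(keys).groups.items():
        sub = table.loc[idx]
        if len(sub) < 2:
            continue
        reports.append(agreement_report(sub[measured_col], sub[predicted_col],
                                        label=str(name), alpha=alpha))
    return reports


@dataclass
class SensitivityReport:
    """Longitudinal sensitivity of the prediction method.

    Compares baseline (T0) and follow-up (T2) whole-body masses obtained by
    the measured (reference) and predicted (three-slice) methods, and tests
    whether the two methods register the same change with a Wilcoxon
    signed-rank test on the paired per-subject deltas.
    """

    n: int
    tissue: str
    measured_t0_mean: float
    measured_t0_sd: float
    measured_t2_mean: float
    measured_t2_sd: float
    predicted_t0_mean: float
    predicted_t0_sd: float
    predicted_t2_mean: float
    predicted_t2_sd: float
    delta_measured_mean: float
    delta_measured_sd: float
    delta_predicted_mean: float
    delta_predicted_sd: float
    delta_gap_mean: float
    delta_gap_sd: float
    wilcoxon_p_measured: float
    wilcoxon_p_predicted: float
    wilcoxon_p_between: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def sensitivity_report(measured_t0, measured_t2, predicted_t0, predicted_t2,
                       tissue: str = "AT") -> SensitivityReport:
    """Build a :class:`SensitivityReport` from paired method series.

    Wilcoxon tests are reported within each method (delta vs zero) and
    between methods (measured delta vs predicted delta, paired).
    """
    m0, m2 = _paired(measured_t0, measured_t2)
    p0, p2 = _paired(predicted_t0, predicted_t2)
    if m0.size != p0.size:
        raise ValueError("measured and predicted series must pair up")
    dm = m2 - m0
    dp = p2 - p0
    sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return SensitivityReport(
        n=int(m0.size), tissue=tissue,
        measured_t0_mean=float(m0.mean()), measured_t0_sd=sd(m0),
        measured_t2_mean=float(m2.mean()), measured_t2_sd=sd(m2),
        predicted_t0_mean=float(p0.mean()), predicted_t0_sd=sd(p0),
        predicted_t2_mean=float(p2.mean()), predicted_t2_sd=sd(p2),
        delta_measured_mean=float(dm.mean()), delta_measured_sd=sd(dm),
        delta_predicted_mean=float(dp.mean()), delta_predicted_sd=sd(dp),
        delta_gap_mean=float((dm - dp).mean()), delta_gap_sd=sd(dm - dp),
        wilcoxon_p_measured=wilcoxon_signed_rank(dm)[0],
        wilcoxon_p_predicted=wilcoxon_signed_rank(dp)[0],
        wilcoxon_p_between=wilcoxon_signed_rank(dm - dp)[0],
    )
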