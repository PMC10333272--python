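"""Whole-body AT/ATFM prediction from three axial slices plus anthropometrics.

The module houses the published best-fit equations (multiple linear
regressions of whole-body adipose tissue, AT, and adipose-tissue-free mass,
ATFM, on age, sex, weight, height and the AT/ATFM masses of the T6-T7,
L4-L5 and mid-thigh slices), applies them to subjects, and re-derives such
models from cohort tables with the same model-building procedure: ordinary
least squares, stepwise variable selection under the Akaike information
criterion, Cook's-distance influence filtering, and residual diagnostics
(Durbin-Watson, Shapiro-Wilk, Bartlett).

Sex is coded 0 for men and 1 for women throughout.  Height is in metres,
weight in kilograms, age in years, slice masses in kilograms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

TOTAL_AT = "TOTAL_AT"
TOTAL_ATFM = "TOTAL_ATFM"

#: Default candidate predictors for model re-derivation.
AT_PREDICTORS = ("age", "sex_code", "weight", "at_t67", "at_l45", "at_thigh")
ATFM_PREDICTORS = ("age", "sex_code", "height", "weight",
                   "atfm_t67", "atfm_l45", "atfm_thigh")
ALL_AT_CANDIDATES = ("age", "sex_code", "height", "weight",
                     "at_t67", "at_l45", "at_thigh")


@dataclass
class SubjectRecord:
    """One subject's covariates and three-slice tissue masses."""

    id: str | int
    age: float
    sex_code: int
    height: float
    weight: float
    at_t67: float
    at_l45: float
    at_thigh: float
    atfm_t67: float
    atfm_l45: float
    atfm_thigh: float
    measured_total_at: float | None = None
    measured_total_atfm: float | None = None

    def __post_init__(self) -> None:
        if self.sex_code not in (0, 1):
            raise ValueError("sex_code must be 0 (male) or 1 (female)")
        if not (1.0 < self.height < 2.3):
            raise ValueError("height must be in metres, within (1.0, 2.3)")
        for name in ("at_t67", "at_l45", "at_thigh",
                     "atfm_t67", "atfm_l45", "atfm_thigh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "id", "age", "sex_code", "height", "weight",
            "at_t67", "at_l45", "at_thigh",
            "atfm_t67", "atfm_l45", "atfm_thigh")}


@dataclass(frozen=True)
class PublishedEquation:
    """An immutable published regression equation."""

    response: str
    intercept: float
    coefficients: Mapping[str, float]
    version: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients",
                           MappingProxyType(dict(self.coefficients)))

    def predict(self, subject) -> float:
        """Evaluate the equation for one subject (record, mapping or row)."""
        value = self.intercept
        for name, coef in self.coefficients.items():
            try:
                x = subject[name] if not hasattr(subject, name) else getattr(subject, name)
            except (KeyError, IndexError):
                raise KeyError(f"subject is missing required field {name!r}") from None
            if x is None or (isinstance(x, float) and np.isnan(x)):
                raise KeyError(f"subject is missing required field {name!r}")
            value += coef * float(x)
        return float(value)

    def predict_frame(self, table: pd.DataFrame) -> pd.Series:
        """Vectorised evaluation over a cohort table."""
        missing = [c for c in self.coefficients if c not in table.columns]
        if missing:
            raise KeyError(f"cohort table is missing column(s) {missing}")
        out = pd.Series(self.intercept, index=table.index, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * table[name].astype(float)
        return out


# Published best-fit equations, as printed in the source text (twice: abstract
# and results).  This "text-v1" variant is the default source of truth.
PUBLISHED_AT = PublishedEquation(
    response=TOTAL_AT,
    intercept=-12.74105,
    coefficients={
        "age": 0.02919,
        "sex_code": 4.27634,
        "weight": 0.22008,
        "at_t67": 26.92234,
        "at_l45": 23.70142,
        "at_thigh": 37.94739,
    },
    version="text-v1",
)

PUBLISHED_ATFM = PublishedEquation(
    response=TOTAL_ATFM,
    intercept=-33.10721,
    coefficients={
        "age": -0.02363,
        "sex_code": -3.58052,
        "height": 30.02252,
        "weight": 0.08549,
        "atfm_t67": 11.36859,
        "atfm_l45": 27.82244,
        "atfm_thigh": 58.62648,
    },
    version="text-v1",
)

# The tabulated variant of the same equations, transcribed verbatim from the
# coefficient table including its printing defects (AT sex coefficient
# 4.24634 rather than 4.27634; the AT L4-L5 column duplicates the mid-thigh
# value 37.94739; the ATFM sex coefficient is printed without the minus sign
# the text carries twice).  Shipped for traceability only.
TABLE_AT = PublishedEquation(
    response=TOTAL_AT,
    intercept=-12.74105,
    coefficients={
        "age": 0.02919,
        "sex_code": 4.24634,
        "weight": 0.22008,
        "at_t67": 26.92234,
        "at_l45": 37.94739,
        "at_thigh": 37.94739,
    },
    version="table-v1",
)

TABLE_ATFM = PublishedEquation(
    response=TOTAL_ATFM,
    intercept=-33.10721,
    coefficients={
        "age": -0.02363,
        "sex_code": 3.58052,
        "height": 30.02252,
        "weight": 0.08549,
        "atfm_t67": 11.36859,
        "atfm_l45": 27.82244,
        "atfm_thigh": 58.62648,
    },
    version="table-v1",
)

EQUATION_VARIANTS: dict[str, dict[str, PublishedEquation]] = {
    "text-v1": {TOTAL_AT: PUBLISHED_AT, TOTAL_ATFM: PUBLISHED_ATFM},
    "table-v1": {TOTAL_AT: TABLE_AT, TOTAL_ATFM: TABLE_ATFM},
}


def predict_total_at(subject, variant: str = "text-v1") -> float:
    """Predicted whole-body adipose tissue mass (kg) for one subject."""
    return EQUATION_VARIANTS[variant][TOTAL_AT].predict(subject)


def predict_total_atfm(subject, variant: str = "text-v1") -> float:
    """Predicted whole-body adipose-tissue-free mass (kg) for one subject."""
    return EQUATION_VARIANTS[variant][TOTAL_ATFM].predict(subject)


@dataclass
class PredictionModel:
    """A fitted linear model for whole-body AT or ATFM."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    n: int
    r2: float
    adjusted_r2: float
    see: float
    aic: float
    retained_predictors: list[str]
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    search_path: list[tuple[str, float]] = field(default_factory=list, repr=False)
    direction: str | None = None
    _sm_result: object = field(default=None, repr=False, compare=False)

    def predict_frame(self, table: pd.DataFrame) -> pd.Series:
        out = pd.Series(self.intercept, index=table.index, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * table[name].astype(float)
        return out

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n": self.n,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "see": self.see,
            "aic": self.aic,
            "retained_predictors": list(self.retained_predictors),
            "direction": self.direction,
        }


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"table is missing predictor column(s) {missing}")
    return sm.add_constant(table[list(predictors)].astype(float), has_constant="add")


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Names of columns involved in an exact linear dependence (via QR)."""
    arr = X.to_numpy(float)
    r = np.linalg.qr(arr, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [X.columns[i] for i, d in enumerate(diag) if d < tol * 1e6]


def aic_gaussian(rss: float, n: int, n_params: int) -> float:
    """AIC under the Gaussian likelihood, in the ``n·ln(RSS/n) + 2·edf``
    convention of R's stepwise selection (``edf`` counts the intercept).

    The additive constant ``n·(ln(2π) + 1)`` is dropped, so values are
    comparable between models fit to the same data but not across software
    that keeps the constant.
    """
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2.0 * n_params


def fit_ols(table: pd.DataFrame, response: str,
            predictors: Sequence[str]) -> PredictionModel:
    """Ordinary least squares of ``response`` on ``predictors``.

    Returns the fitted :class:`PredictionModel` with adjusted R², the
    standard error of estimate ``SEE = sqrt(RSS / (n - p - 1))`` and the AIC
    of :func:`aic_gaussian`.  A rank-deficient design raises with the names
    of the dependent columns.
    """
    if response not in table.columns:
        raise KeyError(f"table is missing response column {response!r}")
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        dupes = sorted({p for p in predictors if predictors.count(p) > 1})
        raise ValueError(f"duplicated predictor column(s): {dupes}")
    X = _design(table, predictors)
    y = table[response].astype(float)
    n, p1 = X.shape
    if n <= p1 + 1:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p1 - 1})")
    if np.linalg.matrix_rank(X.to_numpy(float)) < p1:
        dep = _dependent_columns(X)
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    see = float(np.sqrt(rss / (n - p1)))
    coeffs = {name: float(res.params[name]) for name in predictors}
    return PredictionModel(
        response=response,
        intercept=float(res.params["const"]),
        coefficients=coeffs,
        n=n,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        see=see,
        aic=aic_gaussian(rss, n, p1),
        retained_predictors=predictors,
        fitted=np.asarray(res.fittedvalues, float),
        residuals=np.asarray(res.resid, float),
        _sm_result=res,
    )


def _aic_of(table: pd.DataFrame, response: str, predictors: Sequence[str]) -> float:
    X = _design(table, predictors) if predictors else sm.add_constant(
        pd.DataFrame(index=table.index), has_constant="add")
    y = table[response].astype(float)
    res = sm.OLS(y, X).fit()
    return aic_gaussian(float(res.ssr), len(y), X.shape[1])


def select_stepwise_aic(table: pd.DataFrame, response: str,
                        candidates: Sequence[str] | None = None,
                        direction: str = "both") -> PredictionModel:
    """Greedy AIC-minimising variable selection.

    ``forward`` starts from the intercept-only model and adds terms;
    ``backward`` starts from the full model and drops terms; ``both``
    starts from the full model and considers additions and drops at every
    step.  The search stops when no single move lowers the AIC.  The search
    path (model description, AIC) is recorded on the returned model.
    """
    if candidates is None:
        candidates = list(ALL_AT_CANDIDATES)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must not be empty")
    if direction not in ("forward", "backward", "both"):
        raise ValueError("direction must be 'forward', 'backward' or 'both'")

    current = [] if direction == "forward" else list(candidates)
    current_aic = _aic_of(table, response, current)
    path = [("+".join(current) or "<intercept>", current_aic)]

    while True:
        moves: list[tuple[float, list[str], str]] = []
        if direction in ("forward", "both"):
            for c in candidates:
                if c not in current:
                    trial = current + [c]
                    moves.append((_aic_of(table, response, trial), trial, f"+{c}"))
        if direction in ("backward", "both"):
            for c in current:
                trial = [x for x in current if x != c]
                moves.append((_aic_of(table, response, trial), trial, f"-{c}"))
        if not moves:
            break
        best_aic, best_set, move = min(moves, key=lambda m: m[0])
        if best_aic >= current_aic - 1e-10:
            break
        current, current_aic = best_set, best_aic
        path.append((move, current_aic))

    if current:
        model = fit_ols(table, response, current)
    else:
        y = table[response].astype(float)
        n = len(y)
        resid = (y - y.mean()).to_numpy()
        rss = float(resid @ resid)
        model = PredictionModel(
            response=response, intercept=float(y.mean()), coefficients={},
            n=n, r2=0.0, adjusted_r2=0.0,
            see=float(np.sqrt(rss / (n - 1))), aic=aic_gaussian(rss, n, 1),
            retained_predictors=[], fitted=np.full(n, y.mean()),
            residuals=resid)
    model.search_path = path
    model.direction = direction
    return model


def select_best_aic(table: pd.DataFrame, response: str,
                    candidates: Sequence[str] | None = None
                    ) -> tuple[PredictionModel, dict[str, PredictionModel]]:
    """Run forward, backward and both-direction searches; flag the lowest-AIC
    model as the best fit, mirroring how the published equations were kept."""
    models = {d: select_stepwise_aic(table, response, candidates, d)
              for d in ("forward", "backward", "both")}
    best = min(models.values(), key=lambda m: m.aic)
    return best, models


def cooks_distances(table: pd.DataFrame, response: str,
                    predictors: Sequence[str]) -> pd.Series:
    """Cook's distance of every observation under the OLS fit."""
    model = fit_ols(table, response, predictors)
    infl = model._sm_result.get_influence()  # type: ignore[union-attr]
    d = infl.cooks_distance[0]
    return pd.Series(np.asarray(d, float), index=table.index, name="cooks_d")


def cooks_filter(table: pd.DataFrame, response: str,
                 predictors: Sequence[str],
                 threshold_rule: str | float = "4/n",
                 max_iterations: int = 2,
                 max_removed_fraction: float = 0.10
                 ) -> tuple[pd.DataFrame, list, pd.Series]:
    """Iteratively remove influential observations by Cook's distance.

    ``threshold_rule`` is ``"4/n"`` (default), ``"1"`` (the classic D > 1
    cutoff) or a float.  At most ``max_iterations`` refit rounds are run.
    Removing more than ``max_removed_fraction`` of the rows aborts, guarding
    against degenerate fits.  Returns (filtered table, removed index labels,
    final distances).
    """
    kept = table.copy()
    removed: list = []
    dists = cooks_distances(kept, response, predictors)
    for _ in range(max_iterations):
        n = len(kept)
        if threshold_rule == "4/n":
            thr = 4.0 / n
        else:
            thr = float(threshold_rule)
        dists = cooks_distances(kept, response, predictors)
        flagged = dists.index[dists > thr].tolist()
        if not flagged:
            break
        if (len(removed) + len(flagged)) > max_removed_fraction * len(table):
            raise RuntimeError(
                f"Cook's filtering would remove {len(removed) + len(flagged)} of "
                f"{len(table)} rows (> {max_removed_fraction:.0%}); aborting")
        removed.extend(flagged)
        kept = kept.drop(index=flagged)
    return kept, removed, dists


@dataclass
class DiagnosticsReport:
    """Residual diagnostics: independence, normality, homoscedasticity."""

    n: int
    durbin_watson: float | None
    shapiro_stat: float | None
    shapiro_p: float | None
    bartlett_stat: float | None
    bartlett_p: float | None
    alpha: float
    suppressed: bool = False
    notice: str | None = None

    @property
    def flags(self) -> dict[str, bool]:
        """Pass/fail at ``alpha``; Durbin-Watson passes inside (1.5, 2.5)."""
        if self.suppressed:
            return {}
        return {
            "independence": 1.5 < self.durbin_watson < 2.5,  # type: ignore[operator]
            "normality": self.shapiro_p > self.alpha,  # type: ignore[operator]
            "homoscedasticity": self.bartlett_p > self.alpha,  # type: ignore[operator]
        }


def residual_diagnostics(residuals: np.ndarray | PredictionModel,
                         fitted: np.ndarray | None = None,
                         alpha: float = 0.05) -> DiagnosticsReport:
    """Durbin-Watson, Shapiro-Wilk and Bartlett checks on regression residuals.

    Bartlett's test compares residual variances across tertiles of the fitted
    values (or of the residual order when no fitted values are supplied).
    With fewer than 8 residuals the diagnostics are suppressed with a notice.
    """
    if isinstance(residuals, PredictionModel):
        fitted = residuals.fitted
        residuals = residuals.residuals
    resid = np.asarray(residuals, float)
    n = resid.size
    if n < 8:
        return DiagnosticsReport(n=n, durbin_watson=None, shapiro_stat=None,
                                 shapiro_p=None, bartlett_stat=None,
                                 bartlett_p=None, alpha=alpha, suppressed=True,
                                 notice="fewer than 8 residuals; diagnostics suppressed")
    dw = float(durbin_watson(resid))
    sw_stat, sw_p = stats.shapiro(resid)
    order = np.argsort(fitted) if fitted is not None else np.arange(n)
    groups = np.array_split(resid[order], 3)
    b_stat, b_p = stats.bartlett(*groups)
    return DiagnosticsReport(n=n, durbin_watson=dw,
                             shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
                             bartlett_stat=float(b_stat), bartlett_p=float(b_p),
                             alpha=alpha)
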