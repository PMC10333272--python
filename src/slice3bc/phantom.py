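"""Synthetic phantoms and cohorts with known ground truth.

Every downstream stage of the toolkit (segmentation, volumetrics,
prediction, agreement) is testable without scanner data through three
generators:

* :func:`make_slice_phantom` — an elliptical "body" slice with a bright
  subcutaneous fat ring and optional visceral fat blobs, plus the analytic
  and pixel-counted ground-truth areas;
* :func:`make_slice_series` — a 41-slice whole-body series whose true AT and
  ATFM volumes are obtained by fine numerical integration of the generative
  geometry along the axis (an oracle independent of the frustum estimator);
* :func:`make_cohort` — subject tables whose covariates reproduce the
  development cohort's summary statistics (means, SDs, physiologic ranges)
  and whose measured whole-body masses are the published prediction
  equations plus Gaussian residuals at the published standard errors of
  estimate.

All generators are pure functions of (spec, seed).

The cohort covariates are drawn through a Gaussian copula with
moment-matched truncated-normal marginals: for each covariate the
underlying normal parameters are solved so that the *truncated*
distribution has exactly the target mean and SD within the stated
physiologic range.  Noise on images is additive Gaussian on the magnitude
signal — adequate at phantom signal-to-noise ratios and simpler to reason
about than Rician noise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import SliceImage, TissueMask, indexed_location, L4L5
from .prediction import PUBLISHED_AT, PUBLISHED_ATFM

__all__ = [
    "PhantomSpec", "PhantomTruth", "make_slice_phantom",
    "SeriesProfile", "SeriesTruth", "make_slice_series",
    "CovariateSpec", "CohortSpec", "make_cohort", "make_longitudinal",
    "linear_predictor_sd", "calibrate_slice_sds",
    "REFERENCE_COHORT_COVARIATES", "default_correlation", "COVARIATE_ORDER",
]


# ---------------------------------------------------------------------------
# Slice phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of one synthetic axial slice.

    The body outline is an ellipse with semi-axes ``outer_semiaxes``
    (x = columns, y = rows, in mm).  A subcutaneous fat ring of constant
    thickness lies between the outer ellipse and an inner ellipse whose
    semi-axes are reduced by ``fat_ring_thickness``.  ``visceral_blobs`` are
    fat discs ((cx, cy) mm from the grid centre, radius mm) that must lie
    inside the inner (lean) region and be pairwise disjoint.  Fat is bright:
    ``fat_intensity > lean_intensity > background_intensity``.
    """

    outer_semiaxes: tuple[float, float] = (150.0, 100.0)
    fat_ring_thickness: float = 20.0
    visceral_blobs: tuple[tuple[tuple[float, float], float], ...] = ()
    fat_intensity: float = 1000.0
    lean_intensity: float = 200.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    pixel_spacing: float = 2.0
    grid_shape: tuple[int, int] = (192, 256)

    def __post_init__(self) -> None:
        if not (self.fat_intensity > self.lean_intensity > self.background_intensity):
            raise ValueError("need fat_intensity > lean_intensity > background_intensity "
                             "(fat is bright on the assumed contrast)")
        if not (0 < self.fat_ring_thickness < min(self.outer_semiaxes)):
            raise ValueError("fat_ring_thickness must be positive and smaller "
                             "than the smallest outer semi-axis")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def inner_semiaxes(self) -> tuple[float, float]:
        a, b = self.outer_semiaxes
        t = self.fat_ring_thickness
        return (a - t, b - t)

    def analytic_ring_area_cm2(self) -> float:
        a, b = self.outer_semiaxes
        ai, bi = self.inner_semiaxes
        return np.pi * (a * b - ai * bi) / 100.0

    def analytic_blob_area_cm2(self) -> float:
        return sum(np.pi * r * r for _, r in self.visceral_blobs) / 100.0

    def analytic_at_area_cm2(self) -> float:
        """True adipose area: fat ring plus (disjoint, interior) blobs."""
        return self.analytic_ring_area_cm2() + self.analytic_blob_area_cm2()

    def analytic_body_area_cm2(self) -> float:
        a, b = self.outer_semiaxes
        return np.pi * a * b / 100.0

    def analytic_atfm_area_cm2(self) -> float:
        return self.analytic_body_area_cm2() - self.analytic_at_area_cm2()


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom slice."""

    mask: TissueMask
    analytic_at_area_cm2: float
    analytic_body_area_cm2: float
    pixel_at_area_cm2: float
    pixel_body_area_cm2: float

    @property
    def analytic_atfm_area_cm2(self) -> float:
        return self.analytic_body_area_cm2 - self.analytic_at_area_cm2


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = spec.grid_shape
    s = spec.pixel_spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * s
    x = (np.arange(nx) - (nx - 1) / 2.0) * s
    return np.meshgrid(x, y)  # X, Y in mm, origin at grid centre


def _validate_blobs(spec: PhantomSpec) -> None:
    ai, bi = spec.inner_semiaxes
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    for (cx, cy), r in spec.visceral_blobs:
        if r <= 0:
            raise ValueError("blob radius must be positive")
        bx, by = cx + r * np.cos(theta), cy + r * np.sin(theta)
        if np.any((bx / ai) ** 2 + (by / bi) ** 2 >= 1.0):
            raise ValueError(f"visceral blob at ({cx}, {cy}) r={r} mm is not "
                             "strictly inside the lean (inner) region")
    blobs = list(spec.visceral_blobs)
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            (x1, y1), r1 = blobs[i]
            (x2, y2), r2 = blobs[j]
            if np.hypot(x1 - x2, y1 - y2) <= r1 + r2:
                raise ValueError("visceral blobs must be pairwise disjoint")


def make_slice_phantom(spec: PhantomSpec, seed: int,
                       location: str = L4L5,
                       axial_position_mm: float | None = None,
                       ) -> tuple[SliceImage, PhantomTruth]:
    """Render one phantom slice and its ground truth.

    Identical (spec, seed) pairs yield bit-identical images.  Raises if the
    grid cannot contain the body outline or blobs are invalidly placed.
    """
    a, b = spec.outer_semiaxes
    ny, nx = spec.grid_shape
    s = spec.pixel_spacing
    if 2 * a >= nx * s or 2 * b >= ny * s:
        raise ValueError(
            f"grid {spec.grid_shape} at {s} mm spacing ({nx * s:.0f}×{ny * s:.0f} mm) "
            f"is too small for a body of {2 * a:.0f}×{2 * b:.0f} mm")
    _validate_blobs(spec)

    X, Y = _grid_coords(spec)
    ai, bi = spec.inner_semiaxes
    outer = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    inner = (X / ai) ** 2 + (Y / bi) ** 2 <= 1.0
    at = outer & ~inner
    for (cx, cy), r in spec.visceral_blobs:
        at |= (X - cx) ** 2 + (Y - cy) ** 2 <= r * r

    img = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    img[outer] = spec.lean_intensity
    img[at] = spec.fat_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    px_cm2 = s * s / 100.0
    truth = PhantomTruth(
        mask=TissueMask(at=at, body=outer),
        analytic_at_area_cm2=spec.analytic_at_area_cm2(),
        analytic_body_area_cm2=spec.analytic_body_area_cm2(),
        pixel_at_area_cm2=float(at.sum()) * px_cm2,
        pixel_body_area_cm2=float(outer.sum()) * px_cm2,
    )
    image = SliceImage(pixels=img, pixel_spacing=(s, s), thickness_mm=10.0,
                       location=location, axial_position_mm=axial_position_mm)
    return image, truth


# ---------------------------------------------------------------------------
# Whole-body slice series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesProfile:
    """Axial profile of a whole-body phantom series.

    The base slice geometry is scaled by a factor varying linearly from
    ``scale_start`` (caudal end) to ``scale_end`` (cranial end) along the
    imaged span, scaling semi-axes, ring thickness, and blob centres/radii
    alike — so the cross-sectional areas vary as the square of a linear
    function of axial position.  ``scale_start == scale_end`` gives a
    cylinder, unequal values a cone-like taper.
    """

    base: PhantomSpec = PhantomSpec()
    scale_start: float = 1.0
    scale_end: float = 1.0
    slice_thickness_mm: float = 10.0
    gap_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.scale_start <= 0 or self.scale_end <= 0:
            raise ValueError("scale factors must be positive")
        if self.slice_thickness_mm <= 0 or self.gap_mm < 0:
            raise ValueError("invalid slice geometry")

    def extent_mm(self, n_slices: int) -> float:
        """Imaged axial span: centre-to-centre spacing plus end half-slices."""
        step = self.slice_thickness_mm + self.gap_mm
        return (n_slices - 1) * step + self.slice_thickness_mm

    def scale_at(self, z_mm: float, n_slices: int) -> float:
        f = z_mm / self.extent_mm(n_slices)
        return self.scale_start + (self.scale_end - self.scale_start) * f

    def spec_at(self, z_mm: float, n_slices: int) -> PhantomSpec:
        s = self.scale_at(z_mm, n_slices)
        blobs = tuple(((cx * s, cy * s), r * s) for (cx, cy), r in self.base.visceral_blobs)
        return replace(self.base,
                       outer_semiaxes=(self.base.outer_semiaxes[0] * s,
                                       self.base.outer_semiaxes[1] * s),
                       fat_ring_thickness=self.base.fat_ring_thickness * s,
                       visceral_blobs=blobs)


@dataclass
class SeriesTruth:
    """Analytic whole-body volumes of a phantom series (litres)."""

    at_volume_l: float
    atfm_volume_l: float
    slice_truths: list[PhantomTruth] = field(default_factory=list, repr=False)


def make_slice_series(profile: SeriesProfile, seed: int,
                      n_slices: int = 41, allow_short: bool = False,
                      integration_steps: int = 10_000,
                      ) -> tuple[list[SliceImage], SeriesTruth]:
    """Render a whole-body series and its analytic volume ground truth.

    The reference protocol has 41 slices; other lengths require
    ``allow_short=True``.  True volumes integrate the analytic area profile
    over the imaged span (trapezoid rule, ``integration_steps`` panels) —
    independent of the frustum estimator under test.
    """
    if n_slices != 41 and not allow_short:
        raise ValueError(f"expected 41 slices, got {n_slices}; "
                         "pass allow_short=True for a reduced series")
    if n_slices < 2:
        raise ValueError("a series needs at least 2 slices")

    step = profile.slice_thickness_mm + profile.gap_mm
    half = profile.slice_thickness_mm / 2.0
    centers = half + step * np.arange(n_slices)

    rng = np.random.default_rng(seed)
    images: list[SliceImage] = []
    slice_truths: list[PhantomTruth] = []
    for k, z in enumerate(centers):
        spec_k = profile.spec_at(float(z), n_slices)
        slice_seed = int(rng.integers(0, 2**31 - 1))
        img, truth = make_slice_phantom(spec_k, slice_seed,
                                        location=indexed_location(k),
                                        axial_position_mm=float(z))
        img.thickness_mm = profile.slice_thickness_mm
        images.append(img)
        slice_truths.append(truth)

    zs = np.linspace(0.0, profile.extent_mm(n_slices), integration_steps + 1)
    scales = profile.scale_start + (profile.scale_end - profile.scale_start) * (
        zs / profile.extent_mm(n_slices))
    at_area = profile.base.analytic_at_area_cm2() * scales**2        # cm²
    body_area = profile.base.analytic_body_area_cm2() * scales**2
    # cm² × mm → cm³ via /10, then /1000 → L
    at_vol = float(np.trapezoid(at_area, zs)) / 10.0 / 1000.0
    body_vol = float(np.trapezoid(body_area, zs)) / 10.0 / 1000.0
    truth = SeriesTruth(at_volume_l=at_vol, atfm_volume_l=body_vol - at_vol,
                        slice_truths=slice_truths)
    return images, truth


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Target mean, SD and physiologic range of one covariate."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.lower < self.upper):
            raise ValueError("lower must be below upper")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("mean must lie inside the range")


#: Summary statistics of the development cohort (total population, n = 310):
#: mean, SD and observed range for each covariate of the prediction
#: equations.  Units: years, metres, kilograms.
REFERENCE_COHORT_COVARIATES: dict[str, CovariateSpec] = {
    "age":        CovariateSpec(50.8, 10.6, 20.0, 66.0),
    "height":     CovariateSpec(1.72, 0.08, 1.56, 1.90),
    "weight":     CovariateSpec(93.0, 18.8, 48.0, 152.7),
    "at_t67":     CovariateSpec(0.20, 0.10, 0.01, 0.65),
    "at_l45":     CovariateSpec(0.43, 0.15, 0.07, 0.97),
    "at_thigh":   CovariateSpec(0.17, 0.10, 0.01, 0.59),
    "atfm_t67":   CovariateSpec(0.65, 0.10, 0.39, 0.88),
    "atfm_l45":   CovariateSpec(0.33, 0.06, 0.17, 0.60),
    "atfm_thigh": CovariateSpec(0.36, 0.07, 0.22, 0.56),
}

COVARIATE_ORDER = tuple(REFERENCE_COHORT_COVARIATES)

#: Reference female fraction of the development cohort (70 of 310).
REFERENCE_FEMALE_FRACTION = 70.0 / 310.0

#: Published standard errors of estimate (kg) of the two equations.
REFERENCE_SEE_AT = 2.18
REFERENCE_SEE_ATFM = 2.69

#: Published SDs (kg) of the measured whole-body masses.
REFERENCE_MEASURED_SD_AT = 13.27
REFERENCE_MEASURED_SD_ATFM = 10.29


def default_correlation() -> np.ndarray:
    """Default covariate correlation (order :data:`COVARIATE_ORDER`).

    Only marginal summaries are published for the development cohort, so the
    joint structure is a stated, overridable choice: weight correlates 0.7
    with every slice mass, slice masses correlate 0.5 with each other, and
    all remaining pairs 0.3.  (Weaker slice-slice correlation would make the
    matrix indefinite given six slices each at 0.7 with weight.)
    """
    k = len(COVARIATE_ORDER)
    r = np.full((k, k), 0.3)
    np.fill_diagonal(r, 1.0)
    iw = COVARIATE_ORDER.index("weight")
    slices = [i for i, name in enumerate(COVARIATE_ORDER)
              if name.startswith(("at_", "atfm_"))]
    for i in slices:
        r[iw, i] = r[i, iw] = 0.7
        for j in slices:
            if i != j:
                r[i, j] = 0.5
    return r


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``covariates`` target means/SDs/ranges (defaults: the development
    cohort); ``correlation`` the Gaussian-copula correlation over
    :data:`COVARIATE_ORDER`; ``residual_sd_at``/``residual_sd_atfm`` the SD
    of the Gaussian residual added to the published-equation predictions to
    form the "measured" whole-body masses (defaults: the published SEEs).
    Sex is drawn independently as Bernoulli(``female_fraction``).
    """

    n: int = 310
    female_fraction: float = REFERENCE_FEMALE_FRACTION
    covariates: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(REFERENCE_COHORT_COVARIATES))
    correlation: np.ndarray = field(default_factory=default_correlation)
    residual_sd_at: float = REFERENCE_SEE_AT
    residual_sd_atfm: float = REFERENCE_SEE_ATFM

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be within [0, 1]")
        if self.residual_sd_at < 0 or self.residual_sd_atfm < 0:
            raise ValueError("residual SDs must be non-negative")
        if set(self.covariates) != set(COVARIATE_ORDER):
            raise ValueError(f"covariates must cover exactly {COVARIATE_ORDER}")
        r = np.asarray(self.correlation, float)
        object.__setattr__(self, "correlation", r)
        k = len(COVARIATE_ORDER)
        if r.shape != (k, k) or not np.allclose(r, r.T):
            raise ValueError("correlation must be a symmetric "
                             f"{k}×{k} matrix over {COVARIATE_ORDER}")
        eigs = np.linalg.eigvalsh(r)
        if eigs.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite: "
                             f"smallest eigenvalue {eigs.min():.6f}")


@functools.lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float
                       ) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lower, upper]-truncated normal has the
    requested mean and SD.  Raises if the target is infeasible in the
    truncated-normal family (sd too large for the range)."""
    if sd == 0:
        return mean, 0.0
    if sd >= (upper - lower) / 2.0:
        raise ValueError(f"sd {sd} is not attainable on range ({lower}, {upper})")

    def resid(p):
        mu, lsig = p
        sig = np.exp(lsig)
        a, b = (lower - mu) / sig, (upper - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(resid, x0=[mean, np.log(sd)],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if np.max(np.abs(sol.fun)) > 1e-6 * max(sd, abs(mean), 1e-9):
        raise ValueError(f"could not match mean {mean}, sd {sd} on "
                         f"({lower}, {upper}); residual {sol.fun}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Gaussian-copula draw with moment-matched truncated-normal marginals."""
    k = len(COVARIATE_ORDER)
    # eigh-based transform tolerates positive *semi*-definite correlations
    w, v = np.linalg.eigh(spec.correlation)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((spec.n, k)) @ (v * np.sqrt(w)).T
    u = stats.norm.cdf(z)
    cols = {}
    for j, name in enumerate(COVARIATE_ORDER):
        cov = spec.covariates[name]
        if cov.sd == 0:
            cols[name] = np.full(spec.n, cov.mean)
            continue
        mu, sig = _matched_truncnorm(cov.mean, cov.sd, cov.lower, cov.upper)
        a, b = (cov.lower - mu) / sig, (cov.upper - mu) / sig
        # clip away exact 0/1 quantiles to keep ppf finite
        uj = np.clip(u[:, j], 1e-12, 1 - 1e-12)
        cols[name] = stats.truncnorm.ppf(uj, a, b, loc=mu, scale=sig)
    return pd.DataFrame(cols)


def make_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Generate a subject table with known generative structure.

    Columns: ``id, age, sex_code, height, weight, at_t67, at_l45, at_thigh,
    atfm_t67, atfm_l45, atfm_thigh, measured_total_at, measured_total_atfm``.
    Measured totals are the published equations evaluated on the drawn
    covariates plus independent Gaussian residuals with the spec's SDs.
    """
    rng = np.random.default_rng(seed)
    table = _draw_covariates(spec, rng)
    table.insert(0, "sex_code",
                 (rng.random(spec.n) < spec.female_fraction).astype(int))
    table.insert(0, "id", [f"S{i:04d}" for i in range(spec.n)])
    lp_at = PUBLISHED_AT.predict_frame(table)
    lp_atfm = PUBLISHED_ATFM.predict_frame(table)
    table["measured_total_at"] = lp_at + rng.normal(0, spec.residual_sd_at, spec.n)
    table["measured_total_atfm"] = lp_atfm + rng.normal(0, spec.residual_sd_atfm, spec.n)
    return table


def linear_predictor_sd(spec: CohortSpec, equation, seed: int,
                        n: int = 20_000) -> float:
    """Empirical SD of an equation's linear predictor under the spec.

    Used to calibrate the generator to a target predictor dispersion; the
    estimate is deterministic given (spec, seed).
    """
    big = replace(spec, n=n)
    rng = np.random.default_rng(seed)
    table = _draw_covariates(big, rng)
    table["sex_code"] = (rng.random(n) < spec.female_fraction).astype(int)
    return float(equation.predict_frame(table).std(ddof=1))


def calibrate_slice_sds(spec: CohortSpec, tissue: str,
                        target_predictor_sd: float, seed: int,
                        n_cal: int = 20_000) -> CohortSpec:
    """Scale the three slice-mass SDs of ``tissue`` ("AT" or "ATFM") so the
    corresponding published equation's linear predictor has the target SD.

    Ranges are widened proportionally about the means (lower bounds clipped
    at a small positive mass) and the scale factor is found by bracketed
    root-finding on the empirically simulated predictor SD — deterministic
    given ``seed``.
    """
    if tissue == "AT":
        names, eq = ("at_t67", "at_l45", "at_thigh"), PUBLISHED_AT
    elif tissue == "ATFM":
        names, eq = ("atfm_t67", "atfm_l45", "atfm_thigh"), PUBLISHED_ATFM
    else:
        raise ValueError("tissue must be 'AT' or 'ATFM'")

    def scaled(f: float) -> CohortSpec:
        covs = dict(spec.covariates)
        for name in names:
            c = covs[name]
            lo = max(1e-3, c.mean - (c.mean - c.lower) * f)
            hi = c.mean + (c.upper - c.mean) * f
            covs[name] = CovariateSpec(c.mean, c.sd * f, lo, hi)
        return replace(spec, covariates=covs)

    def gap(f: float) -> float:
        return linear_predictor_sd(scaled(f), eq, seed, n_cal) - target_predictor_sd

    # expand the bracket stepwise: large factors can leave the feasible
    # region of the truncated-normal moment match
    lo, hi = 1.0, 1.0
    g = gap(1.0)
    if g > 0:
        while gap(lo) > 0:
            lo -= 0.1
            if lo < 0.2:
                raise ValueError("target predictor SD too small to calibrate")
    else:
        while gap(hi) < 0:
            hi += 0.1
            if hi > 2.5:
                raise ValueError("target predictor SD too large to calibrate")
    f_star = optimize.brentq(gap, lo, hi, xtol=1e-4)
    return scaled(float(f_star))


# ---------------------------------------------------------------------------
# Longitudinal tables
# ---------------------------------------------------------------------------

def make_longitudinal(cohort: pd.DataFrame,
                      at_delta_mean: float, at_delta_sd: float,
                      atfm_delta_mean: float, atfm_delta_sd: float,
                      seed: int) -> pd.DataFrame:
    """Paired baseline/follow-up (T0/T2) table with injected tissue changes.

    Per-subject changes are Gaussian; follow-up measured totals are baseline
    plus the drawn change, slice masses are co-shifted proportionally (the
    change is assumed uniformly distributed over the body) so the prediction
    equations remain approximately unbiased at follow-up, and weight tracks
    the total mass change.  Columns gain ``_t0``/``_t2`` suffixes.
    """
    for v in (at_delta_mean, at_delta_sd, atfm_delta_mean, atfm_delta_sd):
        if not np.isfinite(v):
            raise ValueError("deltas must be finite")
    if at_delta_sd < 0 or atfm_delta_sd < 0:
        raise ValueError("delta SDs must be non-negative")
    if "measured_total_at" not in cohort or "measured_total_atfm" not in cohort:
        raise ValueError("cohort must carry measured_total_at/atfm columns")

    rng = np.random.default_rng(seed)
    n = len(cohort)
    d_at = rng.normal(at_delta_mean, at_delta_sd, n) if at_delta_sd > 0 \
        else np.full(n, float(at_delta_mean))
    d_atfm = rng.normal(atfm_delta_mean, atfm_delta_sd, n) if atfm_delta_sd > 0 \
        else np.full(n, float(atfm_delta_mean))

    out = pd.DataFrame({"id": cohort["id"].to_numpy(),
                        "age": cohort["age"].to_numpy(),
                        "sex_code": cohort["sex_code"].to_numpy(),
                        "height": cohort["height"].to_numpy()})
    t0_at = cohort["measured_total_at"].to_numpy(float)
    t0_atfm = cohort["measured_total_atfm"].to_numpy(float)
    t2_at = np.maximum(t0_at + d_at, 0.5)
    t2_atfm = np.maximum(t0_atfm + d_atfm, 0.5)
    ratio_at = t2_at / t0_at
    ratio_atfm = t2_atfm / t0_atfm

    out["weight_t0"] = cohort["weight"].to_numpy(float)
    out["weight_t2"] = out["weight_t0"] + (t2_at - t0_at) + (t2_atfm - t0_atfm)
    for col in ("at_t67", "at_l45", "at_thigh"):
        out[f"{col}_t0"] = cohort[col].to_numpy(float)
        out[f"{col}_t2"] = cohort[col].to_numpy(float) * ratio_at
    for col in ("atfm_t67", "atfm_l45", "atfm_thigh"):
        out[f"{col}_t0"] = cohort[col].to_numpy(float)
        out[f"{col}_t2"] = cohort[col].to_numpy(float) * ratio_atfm
    out["measured_total_at_t0"] = t0_at
    out["measured_total_at_t2"] = t2_at
    out["measured_total_atfm_t0"] = t0_atfm
    out["measured_total_atfm_t2"] = t2_atfm
    return out
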