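"""Histogram-threshold segmentation of axial slices into AT and ATFM.

The pipeline mirrors the classic single-expert workflow for T1-like
contrast, where adipose tissue is bright:

1. :func:`body_mask` — the body outline as the largest connected
   above-background component, holes filled;
2. :func:`histogram_threshold` — a fat/lean intensity threshold from the
   body-restricted histogram (Otsu's between-class-variance criterion by
   default, or an explicit valley search);
3. :func:`clean_partial_volume` — removal of small isolated fat components
   (partial-volume speckle);
4. :func:`recover_weak_subcutaneous` — a deterministic surrogate for the
   manual re-inclusion of weak-signal subcutaneous fat: morphological
   closing of the fat label restricted to the peripheral band of the body;
5. :func:`tissue_areas` — per-tissue areas in cm², with AT + ATFM equal to
   the body area by construction.

:func:`segment_slice` composes the stages and logs the decisions taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import filters, measure, morphology

from .core import DensityConstants, SliceImage, SliceComposition, TissueMask
from . import volumetrics


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    ``min_component_px`` defaults to 9 (a 3×3 dot at typical spacing);
    ``ring_width_px`` bounds the peripheral band within which weak
    subcutaneous signal may be recovered.  ``invert=True`` handles
    fat-is-dark contrast by flipping the threshold comparison.
    """

    background_quantile: float = 0.6
    threshold_method: str = "otsu"
    min_component_px: int = 9
    ring_width_px: int = 3
    invert: bool = False
    densities: DensityConstants = field(default_factory=DensityConstants)


class SegmentationError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def body_mask(image: SliceImage, background_quantile: float = 0.6) -> np.ndarray:
    """Body outline: the largest connected above-background component.

    The background level is the given quantile of all pixel intensities;
    pixels strictly above it are candidate tissue.  The largest connected
    component is kept and its holes filled.  Raises if nothing lies above
    background ("empty field of view").
    """
    pixels = image.pixels
    if float(np.ptp(pixels)) == 0.0:
        raise SegmentationError("body_mask: empty field of view "
                                "(image has no intensity variation)")
    level = float(np.quantile(pixels, background_quantile))
    above = pixels > level
    if not above.any():
        raise SegmentationError("body_mask: empty field of view "
                                "(no above-background pixels)")
    # cut speckle and thin noise bridges before picking the main component,
    # so background noise cannot graft a fringe onto the body outline
    opened = ndimage.binary_opening(above, structure=np.ones((3, 3), bool))
    if opened.any():
        above = opened
    labels = measure.label(above, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = int(counts.argmax())
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def _valley_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Deepest histogram valley between the two most prominent peaks."""
    hist, edges = np.histogram(values, bins=bins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, props = find_peaks(smooth, prominence=0.0)
    if len(peaks) < 2:
        # fall back to the histogram midpoint of mass-weighted extremes
        return float(0.5 * (values.min() + values.max()))
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(smooth[p1:p2 + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[valley])


def histogram_threshold(image: SliceImage, body: np.ndarray,
                        method: str = "otsu") -> float:
    """Fat/lean intensity threshold from the body-restricted histogram.

    ``otsu`` maximises between-class variance; ``valley`` takes the deepest
    minimum between the two dominant histogram modes.  The result is
    strictly between the body-restricted min and max.  Raises on a
    degenerate (single-valued) histogram.
    """
    if not body.any():
        raise SegmentationError("histogram_threshold: body mask is empty")
    values = image.pixels[body].astype(float)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise SegmentationError("histogram_threshold: no contrast "
                                "(single-valued histogram inside body)")
    if method == "otsu":
        thr = float(filters.threshold_otsu(values))
    elif method == "valley":
        thr = _valley_threshold(values)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    eps = 1e-9 * (hi - lo)
    return float(np.clip(thr, lo + eps, hi - eps))


def clean_partial_volume(mask: TissueMask, min_component_px: int = 9) -> TissueMask:
    """Drop AT components smaller than ``min_component_px`` pixels.

    Removes partial-volume speckle (isolated bright dots); never adds
    pixels, and is idempotent.
    """
    if min_component_px <= 1:
        return TissueMask(at=mask.at.copy(), body=mask.body.copy())
    labels = measure.label(mask.at, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_component_px
    return TissueMask(at=keep[labels], body=mask.body.copy())


def recover_weak_subcutaneous(mask: TissueMask, ring_width_px: int = 3) -> TissueMask:
    """Re-include weak-signal subcutaneous fat lost to thresholding.

    Morphological closing of the AT label, restricted to the peripheral
    band of the body mask (the inner-boundary ring ``ring_width_px`` wide).
    The closing is taken jointly with the outside-of-body region so that
    signal dropouts at the body surface — where subcutaneous fat sits —
    close against the body boundary.  Interior (visceral) structure is
    untouched and AT never grows outside the body.  Idempotent: closing is
    idempotent and monotone, and the added band is a subset of the closure.
    """
    if ring_width_px < 1:
        return TissueMask(at=mask.at.copy(), body=mask.body.copy())
    selem = morphology.disk(ring_width_px)
    eroded = ndimage.binary_erosion(mask.body, structure=selem, border_value=0)
    band = mask.body & ~eroded
    closed = ndimage.binary_closing(mask.at | ~mask.body,
                                    structure=selem, border_value=1)
    at = mask.at | (closed & band)
    return TissueMask(at=at & mask.body, body=mask.body.copy())


def tissue_areas(mask: TissueMask, pixel_spacing: tuple[float, float]
                 ) -> tuple[float, float]:
    """(AT, ATFM) areas in cm² from pixel counts and spacing (mm)."""
    px_cm2 = pixel_spacing[0] * pixel_spacing[1] / 100.0
    at = float(mask.at.sum()) * px_cm2
    atfm = float(mask.atfm.sum()) * px_cm2
    return at, atfm


def segment_slice(image: SliceImage,
                  config: SegmentationConfig = SegmentationConfig()
                  ) -> tuple[TissueMask, SliceComposition]:
    """Full segmentation of one slice.

    Runs body detection, histogram thresholding, partial-volume cleanup and
    subcutaneous recovery, then converts areas to volumes and masses.  The
    returned composition's ``meta`` records the threshold, method and
    component counts.  Stage failures propagate with the stage name.
    """
    body = body_mask(image, config.background_quantile)
    thr = histogram_threshold(image, body, config.threshold_method)
    if config.invert:
        at_raw = body & (image.pixels < thr)
    else:
        at_raw = body & (image.pixels > thr)
    n_components_raw = int(measure.label(at_raw, connectivity=1).max())
    mask = TissueMask(at=at_raw, body=body)
    mask = clean_partial_volume(mask, config.min_component_px)
    mask = recover_weak_subcutaneous(mask, config.ring_width_px)
    n_components = int(measure.label(mask.at, connectivity=1).max())
    at_area, atfm_area = tissue_areas(mask, image.pixel_spacing)
    comp = volumetrics.compose_slice(
        image.location, at_area, atfm_area,
        thickness_mm=image.thickness_mm, densities=config.densities,
        axial_position_mm=image.axial_position_mm,
        threshold=thr, threshold_method=config.threshold_method,
        at_components_raw=n_components_raw, at_components=n_components)
    return mask, comp
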