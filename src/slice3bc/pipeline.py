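"""End-to-end analysis: images in, body-composition report out.

Composes segmentation → volumetrics → prediction → agreement.  Every report
embeds the configuration snapshot and library versions, and all randomness
flows from the single config seed, so identical inputs yield identical
report bundles.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .core import SliceImage
from .segmentation import segment_slice, SegmentationError
from .volumetrics import (SliceSeries, whole_body_volumes, mass_from_volume,
                          three_slice_masses, AT, ATFM)
from .prediction import EQUATION_VARIANTS, TOTAL_AT, TOTAL_ATFM
from .agreement import agreement_report, subgroup_concordance


def _environment_snapshot(config: RunConfig) -> dict:
    import nibabel, scipy, skimage, statsmodels
    return {
        "config": config.to_dict(),
        "versions": {
            "slice3bc": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "statsmodels": statsmodels.__version__,
            "nibabel": nibabel.__version__,
        },
    }


def _segment_all(images: list[SliceImage], config: RunConfig) -> list:
    comps = []
    for img in images:
        try:
            _, comp = segment_slice(img, config.segmentation)
        except SegmentationError as err:
            raise SegmentationError(f"slice {img.location}: {err}") from err
        comps.append(comp)
    return comps


def analyze_three_slices(images: list[SliceImage], age: float, sex_code: int,
                         height: float, weight: float,
                         config: RunConfig = RunConfig()) -> dict:
    """Segment the three protocol slices and predict whole-body AT/ATFM."""
    comps = _segment_all(images, config)
    masses = three_slice_masses(comps)
    subject = {"age": age, "sex_code": sex_code,
               "height": height, "weight": weight, **masses}
    eqs = EQUATION_VARIANTS[config.equation_variant]
    report = {
        "subject": subject,
        "slices": [{"location": c.location,
                    "at_area_cm2": c.at_area_cm2,
                    "atfm_area_cm2": c.atfm_area_cm2,
                    "at_mass_kg": c.at_mass_kg,
                    "atfm_mass_kg": c.atfm_mass_kg,
                    **c.meta} for c in comps],
        "predicted_total_at_kg": eqs[TOTAL_AT].predict(subject),
        "predicted_total_atfm_kg": eqs[TOTAL_ATFM].predict(subject),
        "equation_variant": config.equation_variant,
    }
    report.update(_environment_snapshot(config))
    return report


def analyze_series(images: list[SliceImage],
                   config: RunConfig = RunConfig(),
                   allow_short: bool = False) -> dict:
    """Whole-body volumes and masses from a 41-slice series."""
    comps = _segment_all(images, config)
    series = SliceSeries(slices=comps, thickness_mm=config.slice_thickness_mm,
                         gap_mm=config.inter_slice_gap_mm,
                         allow_short=allow_short)
    at_l, atfm_l = whole_body_volumes(series)
    report = {
        "n_slices": len(comps),
        "at_volume_l": at_l,
        "atfm_volume_l": atfm_l,
        "at_mass_kg": mass_from_volume(at_l, AT, config.densities),
        "atfm_mass_kg": mass_from_volume(atfm_l, ATFM, config.densities),
    }
    report.update(_environment_snapshot(config))
    return report


def validate_cohort(table: pd.DataFrame,
                    config: RunConfig = RunConfig(),
                    groupings: tuple[str, ...] = ("sex", "bmi_class")) -> dict:
    """Predict whole-body masses for a cohort and report agreement with the
    measured totals, overall and by subgroup."""
    eqs = EQUATION_VARIANTS[config.equation_variant]
    report: dict = {"n": len(table), "equation_variant": config.equation_variant}
    for tissue, response, measured_col in (
            ("at", TOTAL_AT, "measured_total_at"),
            ("atfm", TOTAL_ATFM, "measured_total_atfm")):
        pred = eqs[response].predict_frame(table)
        block: dict = {"predicted_mean": float(pred.mean()),
                       "predicted_sd": float(pred.std(ddof=1))}
        if measured_col in table.columns and table[measured_col].notna().all():
            work = table.copy()
            work["_pred"] = pred
            overall = agreement_report(work[measured_col], work["_pred"])
            block["agreement"] = overall.to_dict()
            block["subgroups"] = {
                g: [r.to_dict() for r in subgroup_concordance(
                    work, measured_col, "_pred", grouping=g,
                    alpha=config.alpha)]
                for g in groupings}
        report[tissue] = block
    report.update(_environment_snapshot(config))
    return report
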