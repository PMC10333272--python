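"""Mid-thigh landmark: half the femoral length, derived from stature.

The mid-thigh slice of the three-slice protocol is positioned at half the
femoral length, which in turn is derived from the subject's stature (cm)
with sex-specific linear formulas.  A configurable reference regression
(e.g. a stature-on-femur line from the forensic literature) can be inverted
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"

STATURE_RANGE_CM = (100.0, 230.0)


def half_femoral_length(stature_cm: float, sex: str) -> float:
    """Half-femoral length (cm) from stature (cm).

    Men: ``(S − 67.76) / 4.4``;  women: ``(S − 61.4) / 4.6``.  Stature must
    be physiologic (100–230 cm); the formulas are only anatomically
    meaningful in centimetres.
    """
    lo, hi = STATURE_RANGE_CM
    if not (lo < stature_cm < hi):
        raise ValueError(f"non-physiologic stature {stature_cm} cm "
                         f"(expected within ({lo:.0f}, {hi:.0f}) cm)")
    if sex == MALE:
        fl = (stature_cm - 67.76) / 4.4
    elif sex == FEMALE:
        fl = (stature_cm - 61.4) / 4.6
    else:
        raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}, got {sex!r}")
    if fl <= 0:
        raise ValueError(f"non-physiologic stature {stature_cm} cm "
                         "(formula yields a non-positive length)")
    return fl


@dataclass(frozen=True)
class ReferenceRegression:
    """A stature-on-femur regression ``S = intercept + slope × femur`` (cm),
    supplied via configuration for comparison against the built-in formula."""

    slope: float
    intercept: float
    name: str = "reference"


def reference_half_femoral_length(stature_cm: float,
                                  reference: ReferenceRegression) -> float:
    """Half-femoral length (cm) by inverting a configured reference line."""
    if reference.slope == 0:
        raise ValueError(f"reference regression {reference.name!r} has zero "
                         "slope and cannot be inverted")
    lo, hi = STATURE_RANGE_CM
    if not (lo < stature_cm < hi):
        raise ValueError(f"non-physiologic stature {stature_cm} cm")
    return (stature_cm - reference.intercept) / (2.0 * reference.slope)


def compare_landmarks(statures_cm: Sequence[float], sexes: Sequence[str],
                      reference: ReferenceRegression) -> pd.DataFrame:
    """Per-subject and summary differences between the built-in formula and a
    configured reference.

    Returns a table with columns ``stature_cm, sex, formula_cm,
    reference_cm, difference_cm``; the summary (mean ± SD of the
    differences) is stored in ``DataFrame.attrs``.
    """
    if len(statures_cm) != len(sexes):
        raise ValueError("statures and sexes must have equal length")
    rows = []
    for s, sex in zip(statures_cm, sexes):
        f = half_femoral_length(s, sex)
        r = reference_half_femoral_length(s, reference)
        rows.append({"stature_cm": s, "sex": sex, "formula_cm": f,
                     "reference_cm": r, "difference_cm": f - r})
    out = pd.DataFrame(rows)
    diffs = out["difference_cm"].to_numpy()
    out.attrs["mean_difference_cm"] = float(np.mean(diffs))
    out.attrs["sd_difference_cm"] = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    out.attrs["reference_name"] = reference.name
    return out
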