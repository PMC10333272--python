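"""Reading and writing slices, cohorts and reports.

NIfTI is the canonical image format (in-plane spacing and slice thickness
live in the header); PNG and CSV grids are accepted for fixtures but need a
sidecar JSON (``<image>.json``) carrying ``pixel_spacing_mm`` and optionally
``thickness_mm``.  Cohorts are CSV tables with a documented snake_case
column schema; reports and ground-truth manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .core import SliceImage, L4L5

#: Required columns of a cohort CSV.
COHORT_COLUMNS = (
    "id", "age", "sex_code", "height", "weight",
    "at_t67", "at_l45", "at_thigh",
    "atfm_t67", "atfm_l45", "atfm_thigh",
)
#: Optional measured whole-body totals.
COHORT_OPTIONAL = ("measured_total_at", "measured_total_atfm")

_SEX_ALIASES = {"m": 0, "male": 0, "0": 0, "f": 1, "female": 1, "1": 1}


def _sidecar(path: Path) -> dict:
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{path.name} has no geometry; provide a sidecar {sidecar.name} "
            'with {"pixel_spacing_mm": [row, col], "thickness_mm": 10.0}')
    return json.loads(sidecar.read_text())


def read_slice(path: str | Path, location: str = L4L5) -> SliceImage:
    """Read one axial slice from NIfTI, PNG or CSV.

    NIfTI spacing comes from the header zooms; PNG/CSV require the sidecar
    JSON.  3-D NIfTI volumes must be single-slice (squeezable to 2-D).
    """
    path = Path(path)
    suffix = path.name.lower()
    if suffix.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj))
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a single slice, got shape {data.shape}")
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        thickness = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 10.0
        return SliceImage(pixels=data.astype(float), pixel_spacing=spacing,
                          thickness_mm=thickness, location=location)
    if suffix.endswith(".png"):
        meta = _sidecar(path)
        data = np.asarray(Image.open(path), dtype=float)
        if data.ndim == 3:  # collapse any colour channels
            data = data[..., 0]
    elif suffix.endswith(".csv"):
        meta = _sidecar(path)
        data = np.loadtxt(path, delimiter=",", dtype=float)
    else:
        raise ValueError(f"unsupported slice format: {path.name}")
    spacing = meta["pixel_spacing_mm"]
    return SliceImage(pixels=data,
                      pixel_spacing=(float(spacing[0]), float(spacing[1])),
                      thickness_mm=float(meta.get("thickness_mm", 10.0)),
                      location=meta.get("location", location))


def write_slice(image: SliceImage, path: str | Path) -> Path:
    """Write a slice as NIfTI, PNG (integer intensities) or CSV.

    Non-NIfTI formats get a sidecar JSON with the geometry.  Integer-valued
    images round-trip bit-exactly through PNG (16-bit).
    """
    path = Path(path)
    suffix = path.name.lower()
    if suffix.endswith((".nii", ".nii.gz")):
        affine = np.diag([image.pixel_spacing[0], image.pixel_spacing[1],
                          image.thickness_mm, 1.0])
        # store as a single-slice 3-D volume so the thickness lives in the
        # third header zoom
        data = image.pixels.astype(np.float64)[..., np.newaxis]
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((image.pixel_spacing[0], image.pixel_spacing[1],
                              image.thickness_mm))
        nib.save(img, str(path))
        return path
    meta = {"pixel_spacing_mm": list(image.pixel_spacing),
            "thickness_mm": image.thickness_mm,
            "location": image.location}
    if suffix.endswith(".png"):
        data = np.asarray(image.pixels)
        if not np.issubdtype(data.dtype, np.integer):
            data = np.clip(np.round(data), 0, 65535)
        Image.fromarray(data.astype(np.uint16)).save(path)
    elif suffix.endswith(".csv"):
        np.savetxt(path, image.pixels, delimiter=",", fmt="%.10g")
    else:
        raise ValueError(f"unsupported slice format: {path.name}")
    path.with_name(path.name + ".json").write_text(json.dumps(meta))
    return path


def read_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Sex may be coded ``M``/``F`` (mapped to 0/1) or 0/1 directly.  Height
    must be in metres — values that look like centimetres are rejected with
    a unit hint.  Out-of-range weights raise per-row warnings (or errors
    when ``strict``).
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: malformed header, missing column(s) {missing}")

    sex = table["sex_code"]
    if sex.dtype == object:
        mapped = sex.astype(str).str.strip().str.lower().map(_SEX_ALIASES)
        if mapped.isna().any():
            bad = sorted(sex[mapped.isna()].unique().tolist())
            raise ValueError(f"{path.name}: unrecognised sex codes {bad}")
        table["sex_code"] = mapped.astype(int)
    if not table["sex_code"].isin((0, 1)).all():
        raise ValueError(f"{path.name}: sex_code must be 0 (male) or 1 (female)")

    problems = []
    for i, h in table["height"].items():
        if not (1.0 < h < 2.3):
            hint = " (looks like centimetres; heights must be metres)" if 100 < h < 230 else ""
            problems.append(f"row {i}: height {h}{hint}")
    for i, w in table["weight"].items():
        if not (40.0 <= w <= 200.0):
            problems.append(f"row {i}: weight {w} kg outside (40, 200)")
    if problems:
        msg = f"{path.name}: out-of-range values:\n  " + "\n  ".join(problems)
        if strict:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    """Write a report or ground-truth manifest as indented JSON."""
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
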