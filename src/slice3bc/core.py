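"""Core data containers shared by the segmentation, volumetric and phantom modules.

The toolkit works on single axial MR slices.  A :class:`SliceImage` couples an
intensity grid with its geometry (in-plane pixel spacing, slice thickness and
an anatomical location label); a :class:`TissueMask` is the result of
segmenting such a slice into adipose tissue (AT) and everything else inside
the body outline (adipose-tissue-free mass, ATFM); a
:class:`SliceComposition` carries the derived areas, volumes and masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical anatomical location labels for the three-slice protocol.
T6T7 = "T6T7"
L4L5 = "L4L5"
MIDTHIGH = "MIDTHIGH"
THREE_SLICE_LOCATIONS = (T6T7, L4L5, MIDTHIGH)


def indexed_location(k: int) -> str:
    """Label for slice ``k`` of a whole-body multi-slice series."""
    return f"INDEXED({int(k)})"


@dataclass(frozen=True)
class DensityConstants:
    """Tissue densities used to convert volumes to masses.

    Defaults are the constant densities conventionally assumed in MR
    volumetry: 0.92 kg/L for adipose tissue and 1.04 kg/L for lean tissue.
    """

    fat: float = 0.92
    lean: float = 1.04

    def __post_init__(self) -> None:
        if self.fat <= 0 or self.lean <= 0:
            raise ValueError("densities must be positive")


@dataclass
class SliceImage:
    """One axial MR slice: an intensity grid plus its geometry.

    Parameters
    ----------
    pixels
        2-D array of signal intensities (arbitrary units).
    pixel_spacing
        (row, col) in-plane spacing in millimetres.
    thickness_mm
        Slice thickness in millimetres (the protocol uses 10 mm).
    location
        Anatomical label: ``"T6T7"``, ``"L4L5"``, ``"MIDTHIGH"`` or
        ``indexed_location(k)`` for series slices.
    axial_position_mm
        Optional axial (cranio-caudal) position of the slice centre.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    thickness_mm: float = 10.0
    location: str = L4L5
    axial_position_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class TissueMask:
    """Binary adipose-tissue labelling of a slice.

    ``at`` marks adipose-tissue pixels, ``body`` the full body outline;
    adipose pixels are always inside the body (``at ⊆ body``).
    """

    at: np.ndarray
    body: np.ndarray

    def __post_init__(self) -> None:
        self.at = np.asarray(self.at, dtype=bool)
        self.body = np.asarray(self.body, dtype=bool)
        if self.at.shape != self.body.shape:
            raise ValueError("at and body masks must share a shape")
        if np.any(self.at & ~self.body):
            raise ValueError("adipose mask extends outside the body mask")

    @property
    def atfm(self) -> np.ndarray:
        """Adipose-tissue-free pixels (body minus AT)."""
        return self.body & ~self.at


@dataclass
class SliceComposition:
    """Tissue content of one slice: areas (cm²), volumes (L), masses (kg)."""

    location: str
    at_area_cm2: float
    atfm_area_cm2: float
    at_volume_l: float
    atfm_volume_l: float
    at_mass_kg: float
    atfm_mass_kg: float
    thickness_mm: float = 10.0
    axial_position_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("at_area_cm2", "atfm_area_cm2", "at_volume_l",
                     "atfm_volume_l", "at_mass_kg", "atfm_mass_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def body_area_cm2(self) -> float:
        return self.at_area_cm2 + self.atfm_area_cm2
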