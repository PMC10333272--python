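"""Slice areas to volumes and masses; whole-body truncated-pyramid reconstruction.

Whole-body volumetry from an axial multi-slice series follows the truncated
pyramid (frustum) rule: the volume between two consecutive slices with areas
``A1`` and ``A2`` a distance ``h`` apart is ``(h/3)(A1 + A2 + sqrt(A1*A2))``.
The reference protocol uses 41 slices of 10 mm thickness spaced by a 40 mm
gap, i.e. 50 mm centre to centre; the first and last slice additionally
contribute their own half-thickness prisms so the reconstructed extent covers
the full imaged span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (DensityConstants, SliceComposition, THREE_SLICE_LOCATIONS,
                   T6T7, L4L5, MIDTHIGH)

#: Tissue labels accepted by :func:`mass_from_volume`.
AT = "AT"
ATFM = "ATFM"

#: Default number of slices of the whole-body reference protocol.
REFERENCE_SERIES_LENGTH = 41


def slice_volume(area_cm2: float, thickness_mm: float = 10.0) -> float:
    """Volume (L) of one slice: area × thickness (1 L = 1000 cm³)."""
    if area_cm2 < 0:
        raise ValueError("area must be non-negative")
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return area_cm2 * (thickness_mm / 10.0) / 1000.0


def frustum_volume(a1_cm2: float, a2_cm2: float, h_cm: float) -> float:
    """Truncated-pyramid volume (L) between two parallel sections.

    ``V = (h/3)(A1 + A2 + sqrt(A1*A2))`` — exact for any solid whose section
    area is the square of a linear function of axial position (prisms,
    pyramids, cones and their frusta).
    """
    if a1_cm2 < 0 or a2_cm2 < 0:
        raise ValueError("section areas must be non-negative")
    if h_cm <= 0:
        raise ValueError("height must be positive")
    return (h_cm / 3.0) * (a1_cm2 + a2_cm2 + (a1_cm2 * a2_cm2) ** 0.5) / 1000.0


def mass_from_volume(volume_l: float, tissue: str,
                     densities: DensityConstants = DensityConstants()) -> float:
    """Convert a tissue volume (L) to mass (kg) using the constant densities."""
    if volume_l < 0:
        raise ValueError("volume must be non-negative")
    if tissue == AT:
        return densities.fat * volume_l
    if tissue == ATFM:
        return densities.lean * volume_l
    raise ValueError(f"unknown tissue label {tissue!r} (expected 'AT' or 'ATFM')")


def compose_slice(location: str, at_area_cm2: float, atfm_area_cm2: float,
                  thickness_mm: float = 10.0,
                  densities: DensityConstants = DensityConstants(),
                  axial_position_mm: float | None = None,
                  **meta) -> SliceComposition:
    """Build a :class:`SliceComposition` from per-tissue areas."""
    at_vol = slice_volume(at_area_cm2, thickness_mm)
    atfm_vol = slice_volume(atfm_area_cm2, thickness_mm)
    return SliceComposition(
        location=location,
        at_area_cm2=at_area_cm2,
        atfm_area_cm2=atfm_area_cm2,
        at_volume_l=at_vol,
        atfm_volume_l=atfm_vol,
        at_mass_kg=mass_from_volume(at_vol, AT, densities),
        atfm_mass_kg=mass_from_volume(atfm_vol, ATFM, densities),
        thickness_mm=thickness_mm,
        axial_position_mm=axial_position_mm,
        meta=dict(meta),
    )


@dataclass
class SliceSeries:
    """Ordered whole-body series of slice compositions.

    The expected length is 41 (the reference protocol); shorter series are
    accepted only with ``allow_short=True`` so that reduced test series are an
    explicit choice, never an accident.
    """

    slices: list[SliceComposition]
    thickness_mm: float = 10.0
    gap_mm: float = 40.0
    allow_short: bool = False

    def __post_init__(self) -> None:
        if len(self.slices) != REFERENCE_SERIES_LENGTH and not self.allow_short:
            raise ValueError(
                f"expected {REFERENCE_SERIES_LENGTH} slices, got {len(self.slices)}; "
                "pass allow_short=True for a reduced series")
        if len(self.slices) < 2:
            raise ValueError("a series needs at least 2 slices")
        positions = [s.axial_position_mm for s in self.slices]
        if all(p is not None for p in positions):
            diffs = [b - a for a, b in zip(positions, positions[1:])]  # type: ignore[operator]
            if any(d <= 0 for d in diffs):
                raise ValueError("axial positions must be strictly increasing")

    @property
    def inter_slice_distance_mm(self) -> float:
        """Centre-to-centre distance: thickness + gap."""
        return self.thickness_mm + self.gap_mm


def whole_body_volumes(series: SliceSeries) -> tuple[float, float]:
    """Reconstruct whole-body (AT, ATFM) volumes in litres.

    Consecutive slice pairs contribute frusta over the centre-to-centre
    distance; the two end slices contribute their own half-thickness prisms
    (end caps), so a constant-area 41-slice series of area A reduces to
    ``A × (40 × 50 mm + 10 mm)`` exactly.
    """
    h_cm = series.inter_slice_distance_mm / 10.0
    at = 0.0
    atfm = 0.0
    for a, b in zip(series.slices, series.slices[1:]):
        if a.axial_position_mm is not None and b.axial_position_mm is not None:
            h_cm = (b.axial_position_mm - a.axial_position_mm) / 10.0
        at += frustum_volume(a.at_area_cm2, b.at_area_cm2, h_cm)
        atfm += frustum_volume(a.atfm_area_cm2, b.atfm_area_cm2, h_cm)
    cap_mm = series.thickness_mm / 2.0
    for end in (series.slices[0], series.slices[-1]):
        at += slice_volume(end.at_area_cm2, cap_mm)
        atfm += slice_volume(end.atfm_area_cm2, cap_mm)
    return at, atfm


def three_slice_masses(slices: list[SliceComposition]) -> dict[str, float]:
    """Per-slice AT/ATFM masses (kg) for the three-slice prediction inputs.

    Requires exactly one slice at each of T6-T7, L4-L5 and mid-thigh; returns
    the ``at_t67 … atfm_thigh`` fields of a subject record.
    """
    by_loc: dict[str, SliceComposition] = {}
    for s in slices:
        if s.location in by_loc:
            raise ValueError(f"duplicate slice location {s.location!r}")
        by_loc[s.location] = s
    missing = [loc for loc in THREE_SLICE_LOCATIONS if loc not in by_loc]
    if missing:
        raise ValueError(f"missing slice location(s): {', '.join(missing)}")
    extra = set(by_loc) - set(THREE_SLICE_LOCATIONS)
    if extra:
        raise ValueError(f"unexpected slice location(s): {sorted(extra)}")
    key = {T6T7: "t67", L4L5: "l45", MIDTHIGH: "thigh"}
    out: dict[str, float] = {}
    for loc, comp in by_loc.items():
        out[f"at_{key[loc]}"] = comp.at_mass_kg
        out[f"atfm_{key[loc]}"] = comp.atfm_mass_kg
    return out
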