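"""Morphometric cross-sections of the force-transmitting pad structures.

Bundled measurement table emulating the published cross-sectional areas of
the three structures that carry attachment loads in the digital pad:

* ventral collagen layer - transverse section at its thinnest point below
  the base of the distal phalanx (20,000-65,000 um^2, collagen tensile
  strength taken as 100 MPa);
* collagenous septum - horizontal section (6,500-7,500 um^2, same assumed
  strength as collagen);
* dorsoventral smooth-muscle bundles traversing the lymph space - total
  horizontal section (7,000-14,000 um^2, skeletal-muscle tensile strength
  0.2-0.4 MPa).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SectionMeasurement", "morphometry_fixture", "fixture_frame"]

STRUCTURES = ("ventral_collagen_layer", "septum", "dorsoventral_muscle_bundles")


@dataclass(frozen=True)
class SectionMeasurement:
    """A named structure with measured area range and assumed tensile strength."""

    structure: str
    area_um2_min: float
    area_um2_max: float
    strength_MPa_min: float
    strength_MPa_max: float
    source_digits: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.area_um2_min <= self.area_um2_max):
            raise ValueError("areas must be positive with min <= max")
        if not (0 < self.strength_MPa_min <= self.strength_MPa_max):
            raise ValueError("strengths must be positive with min <= max")


def morphometry_fixture() -> list[SectionMeasurement]:
    """The three bundled section measurements (areas in um^2, strengths in MPa)."""
    return [
        SectionMeasurement(
            "ventral_collagen_layer", 20_000, 65_000, 100.0, 100.0,
            source_digits="digits F_III, H_II, H_V of frog 3",
        ),
        SectionMeasurement(
            "septum", 6_500, 7_500, 100.0, 100.0,
            source_digits="digits F_III of frog 1, H_V of frog 3",
        ),
        SectionMeasurement(
            "dorsoventral_muscle_bundles", 7_000, 14_000, 0.2, 0.4,
            source_digits="digits F_I, H_V of frog 3, F_I of frog 1",
        ),
    ]


def fixture_frame() -> pd.DataFrame:
    """Morphometry fixture as a DataFrame (CSV-exportable)."""
    rows = morphometry_fixture()
    return pd.DataFrame(
        {
            "structure": [r.structure for r in rows],
            "area_um2_min": [r.area_um2_min for r in rows],
            "area_um2_max": [r.area_um2_max for r in rows],
            "strength_MPa_min": [r.strength_MPa_min for r in rows],
            "strength_MPa_max": [r.strength_MPa_max for r in rows],
        }
    )
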