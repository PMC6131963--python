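"""Tensile-capacity load budgets of the force-transmitting pad structures.

A plain strength-of-materials bound: the tensile capacity of a structure is
its measured cross-sectional area times its assumed tensile strength
(1 um^2 x 1 MPa = 1e-6 N).  Capacities are compared against reference
demands such as the 1.27 N maximum load measured on single digital pads of
Trachycephalus resinifictrix and the per-digit share of body weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .morphometry import SectionMeasurement, morphometry_fixture

__all__ = [
    "LoadBudget",
    "tensile_capacity",
    "per_digit_load",
    "budget_report",
    "budget_frame",
]

UM2_MPA_TO_N = 1e-6
G_MS2 = 9.81


@dataclass(frozen=True)
class LoadBudget:
    """Capacity range of one structure against one reference demand."""

    structure: str
    capacity_N_min: float
    capacity_N_max: float
    demand_N: float
    sufficient: bool

    @property
    def safety_factor_min(self) -> float:
        return self.capacity_N_min / self.demand_N if self.demand_N > 0 else float("inf")

    @property
    def safety_factor_max(self) -> float:
        return self.capacity_N_max / self.demand_N if self.demand_N > 0 else float("inf")


def tensile_capacity(area_um2: float, strength_MPa: float) -> float:
    """Force (N) a section of given area (um^2) bears at a tensile strength (MPa)."""
    if area_um2 <= 0 or strength_MPa <= 0:
        raise ValueError("area and strength must be positive")
    return area_um2 * strength_MPa * UM2_MPA_TO_N


def per_digit_load(body_mass_g: float = 7.0, n_digits: int = 18, g_ms2: float = G_MS2) -> float:
    """Body weight (N) distributed uniformly over all digits.

    The published load case uses 7 g x 9.81 m s^-2 / 18 digits = 3.815 mN.
    """
    if body_mass_g < 0:
        raise ValueError("body mass must be non-negative")
    if n_digits < 1:
        raise ValueError("n_digits must be >= 1")
    return body_mass_g * 1e-3 * g_ms2 / n_digits


def budget_report(
    fixture: list[SectionMeasurement] | None = None,
    reference_loads: dict[str, float] | None = None,
    *,
    include_complex: bool = True,
) -> list[LoadBudget]:
    """One LoadBudget per structure per reference load.

    ``sufficient`` flags capacity_min >= demand.  With ``include_complex``
    the septum and dorsoventral muscle bundles are also reported summed (the
    muscle-septum complex that jointly carries the normal load on a digit).
    """
    if fixture is None:
        fixture = morphometry_fixture()
    if reference_loads is None:
        reference_loads = {
            "single_pad_max_load": 1.27,
            "per_digit_body_weight": per_digit_load(),
        }
    rows: list[tuple[str, float, float]] = [
        (
            m.structure,
            tensile_capacity(m.area_um2_min, m.strength_MPa_min),
            tensile_capacity(m.area_um2_max, m.strength_MPa_max),
        )
        for m in fixture
    ]
    if include_complex:
        parts = {s: (lo, hi) for s, lo, hi in rows}
        if "septum" in parts and "dorsoventral_muscle_bundles" in parts:
            lo = parts["septum"][0] + parts["dorsoventral_muscle_bundles"][0]
            hi = parts["septum"][1] + parts["dorsoventral_muscle_bundles"][1]
            rows.append(("muscle_septum_complex", lo, hi))
    out = []
    for structure, cap_lo, cap_hi in rows:
        for demand in reference_loads.values():
            out.append(
                LoadBudget(
                    structure=structure,
                    capacity_N_min=cap_lo,
                    capacity_N_max=cap_hi,
                    demand_N=demand,
                    sufficient=cap_lo >= demand,
                )
            )
    return out


def budget_frame(budgets: list[LoadBudget]) -> pd.DataFrame:
    """Budget report as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        {
            "structure": [b.structure for b in budgets],
            "capacity_N_min": [b.capacity_N_min for b in budgets],
            "capacity_N_max": [b.capacity_N_max for b in budgets],
            "demand_N": [b.demand_N for b in budgets],
            "sufficient": [b.sufficient for b in budgets],
        }
    )
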