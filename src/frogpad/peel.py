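"""Peeling mechanics of the digital pad.

Two complementary views of detachment:

* the Kendall thin-film peel relation - for an elastic strip of width b,
  thickness d and modulus E adhering with energy R per unit area, the steady
  peel force F at angle theta satisfies

      (F/b)^2 / (2 d E) + (F/b) (1 - cos theta) - R = 0,

  whose positive root decreases monotonically with theta: pulling at a
  large peel angle (> 90 deg) lowers the force needed to peel;

* a septum-loading contact-stress comparison - the pad block is loaded
  either through the septum's ventral attachment line (a dorsodistal pull on
  the dorsal surface, the hypothesised detachment manoeuvre) or through the
  proximal end face with the same force magnitude, and the normal (pull-off)
  tractions on the fixed ventral contact surface are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .geometry import DesignDomain

__all__ = [
    "PeelConfig",
    "kendall_peel_force",
    "VentralTraction",
    "ContactStressReport",
    "septum_load_case",
    "ventral_normal_traction",
    "septum_loadcase_comparison",
]

J_PER_M2_TO_N_PER_MM = 1e-3


@dataclass(frozen=True)
class PeelConfig:
    """Kendall peel-strip parameters (mm-MPa internally, R given in J m^-2)."""

    width_b_mm: float
    thickness_d_mm: float
    E_MPa: float
    R_Jm2: float
    theta_deg: float

    def __post_init__(self) -> None:
        for name in ("width_b_mm", "thickness_d_mm", "E_MPa", "R_Jm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.theta_deg <= 180:
            raise ValueError("theta_deg must lie in [0, 180]")


def kendall_peel_force(config: PeelConfig) -> float:
    """Steady-state peel force F (N): the positive root of the Kendall quadratic.

    At theta = 0 only the elastic term resists (F/b = sqrt(2 R d E)); in the
    inextensible limit d E -> inf the force tends to b R / (1 - cos theta).
    """
    dE = config.thickness_d_mm * config.E_MPa  # N/mm
    R = config.R_Jm2 * J_PER_M2_TO_N_PER_MM  # N/mm
    a = 1.0 - np.cos(np.radians(config.theta_deg))
    # rationalised root: stable in the inextensible limit d*E -> inf
    f = 2.0 * R / (a + np.sqrt(a * a + 2.0 * R / dE))  # F/b, N/mm
    return float(config.width_b_mm * f)


# ---------------------------------------------------------------------------
# septum load-case comparison
# ---------------------------------------------------------------------------

@dataclass
class VentralTraction:
    """Normal traction on the fixed ventral contact face of one load case.

    ``normal_MPa`` is nodal, tension (pull-off) positive: the z-reaction the
    substrate exerts on the pad, negated, divided by the nodal tributary
    area.  Its area integral balances the applied load's normal component.
    """

    node_x_mm: np.ndarray  # (nnx,)
    node_y_mm: np.ndarray  # (nny,)
    normal_MPa: np.ndarray  # (nnx, nny)
    area_mm2: np.ndarray  # tributary areas
    applied_force_N: np.ndarray

    @property
    def total_normal_N(self) -> float:
        return float((self.normal_MPa * self.area_mm2).sum())

    @property
    def max_tensile_MPa(self) -> float:
        return float(self.normal_MPa.max())

    @property
    def max_tensile_location_mm(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.normal_MPa), self.normal_MPa.shape)
        return float(self.node_x_mm[i]), float(self.node_y_mm[j])

    @property
    def mean_tensile_MPa(self) -> float:
        """Area-weighted mean of the tensile (pull-off) part of the traction."""
        a = self.area_mm2
        return float((np.maximum(self.normal_MPa, 0.0) * a).sum() / a.sum())

    @property
    def mean_signed_MPa(self) -> float:
        a = self.area_mm2
        return float((self.normal_MPa * a).sum() / a.sum())


@dataclass
class ContactStressReport:
    """Side-by-side ventral tractions under septum vs proximal-pull loading."""

    septum: VentralTraction
    proximal_pull: VentralTraction

    @property
    def septum_peaks_proximally(self) -> bool:
        """Is the septum case's tensile maximum in the proximal 10% of the face?"""
        x, _ = self.septum.max_tensile_location_mm
        length = self.septum.node_x_mm[-1]
        return x <= 0.1 * length

    @property
    def mean_tensile_ratio(self) -> float:
        return self.septum.mean_tensile_MPa / self.proximal_pull.mean_tensile_MPa


def septum_load_case(
    domain: DesignDomain,
    force_N: float = 3.815e-3,
    attachment_frac: float = 0.25,
    inclination_deg: float = 70.0,
) -> fem.LoadCase:
    """Dorsodistal pull along the septum's ventral attachment line.

    The septum is idealised as a rigid cross-lateral line on the dorsal face
    of the pad block at ``attachment_frac`` of the pad length; the pull is
    directed dorsodistally at ``inclination_deg`` above the ventral plane
    (70 deg by default, i.e. 90 deg minus the ~20 deg septum-plane rotation
    about the transverse pad axis).  The attachment defaults to a quarter of
    the pad length: the mucus ducts open distally of the septum, so its
    ventral attachment sits just proximal of the duct field.
    """
    nx, ny, nz = domain.resolution
    hx, _, _ = domain.voxel_size
    p = domain.params
    x_att = attachment_frac * p.length_mm
    if not 0 <= x_att <= p.length_mm:
        raise ValueError("attachment line outside the pad length")
    ix = int(round(x_att / hx))
    ix = min(max(ix, 0), nx)
    # nodes of the attachment line that touch solid material on the dorsal face
    touch = np.zeros(ny + 1, dtype=bool)
    solid_top = domain.solid_mask[:, :, nz - 1]
    for ex in (ix - 1, ix):
        if 0 <= ex < nx:
            touch[:-1] |= solid_top[ex]
            touch[1:] |= solid_top[ex]
    iy = np.nonzero(touch)[0]
    if iy.size == 0:
        raise ValueError("attachment line does not touch solid material")
    nodes = fem.node_index(domain.resolution, np.full(iy.shape, ix), iy, np.full(iy.shape, nz))
    th = np.radians(inclination_deg)
    force = (force_N * np.cos(th), 0.0, force_N * np.sin(th))
    return fem.LoadCase(
        line_loads=(fem.LineLoad(node_ids=tuple(int(n) for n in nodes),
                                 force_N=force, label="septum"),),
    )


def ventral_normal_traction(u: fem.DisplacementField) -> VentralTraction:
    """Recover the nodal normal contact traction on the fixed ventral face."""
    domain = u.domain
    nx, ny, nz = domain.resolution
    hx, hy, _ = domain.voxel_size
    quads = fem._boundary_face_quads(domain, "ventral")
    area = np.zeros((nx + 1) * (ny + 1) * (nz + 1))
    np.add.at(area, quads.ravel(), hx * hy / 4.0)
    ventral_nodes = fem.face_nodes(domain.resolution, "ventral")
    rz = u.reactions[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tz = np.where(area > 0, -rz / np.where(area > 0, area, 1.0), 0.0)
    grid = tz[ventral_nodes].reshape(nx + 1, ny + 1)
    agrid = area[ventral_nodes].reshape(nx + 1, ny + 1)
    return VentralTraction(
        node_x_mm=np.arange(nx + 1) * hx,
        node_y_mm=np.arange(ny + 1) * hy,
        normal_MPa=grid,
        area_mm2=agrid,
        applied_force_N=u.load.reshape(-1, 3).sum(axis=0),
    )


def septum_loadcase_comparison(
    domain: DesignDomain,
    material: fem.Material,
    force_N: float = 3.815e-3,
    attachment_frac: float = 0.25,
    inclination_deg: float = 70.0,
    *,
    penalty_p: float = 3.0,
) -> ContactStressReport:
    """Compare ventral pull-off tractions: septum pull vs equal-magnitude proximal pull."""
    case_a = septum_load_case(domain, force_N, attachment_frac, inclination_deg)
    case_b = fem.LoadCase(
        tractions=(fem.FaceTraction(face="proximal", force_N=(-force_N, 0.0, 0.0)),),
    )
    ua = fem.solve(domain, material, case_a, penalty_p)
    ub = fem.solve(domain, material, case_b, penalty_p)
    return ContactStressReport(
        septum=ventral_normal_traction(ua),
        proximal_pull=ventral_normal_traction(ub),
    )
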