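"""Stiffness-maximising topology optimisation of the pad domain.

Compliance minimisation under a volume constraint via SIMP (penalty p = 3)
with optimality-criteria density updates and a linear-decay sensitivity
filter.  The published schedule is followed: the initial solid volume is
reduced in 2.5% stages down to 40%, each stage iterated to convergence
before the next volume decrement.  Mid-sagittal mirror symmetry is enforced
after every update, and the ventral voxel layer is frozen at full density
(removal of the ventral model surface prohibited).  The algorithm contains
no randomness: identical inputs give identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from . import fem
from .geometry import DesignDomain

__all__ = [
    "OptimisationSchedule",
    "OptimisationResult",
    "compliance_and_sensitivity",
    "filter_sensitivities",
    "update_densities",
    "optimise",
]

log = logging.getLogger(__name__)

RHO_MIN = 1e-3  # lower density bound for design voxels
OC_MOVE = 0.2
OC_DAMPING = 0.5
OC_BISECT_TOL = 1e-6


@dataclass(frozen=True)
class OptimisationSchedule:
    """Stepped volume-reduction schedule (published values: 60% in 2.5% steps)."""

    total_reduction: float = 0.60
    step: float = 0.025
    inner_iters_max: int = 30
    convergence_tol: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.total_reduction < 1:
            raise ValueError("require 0 < step <= total_reduction < 1")
        n = self.total_reduction / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_reduction must be an integer multiple of step")
        if self.inner_iters_max < 1:
            raise ValueError("inner_iters_max must be >= 1")

    @property
    def n_stages(self) -> int:
        return int(round(self.total_reduction / self.step))

    def targets(self) -> np.ndarray:
        """Volume-fraction target per stage (fractions of the initial solid volume)."""
        return 1.0 - self.step * np.arange(1, self.n_stages + 1)


@dataclass
class OptimisationResult:
    """Per-stage snapshots of the stepped optimisation."""

    domain: DesignDomain
    volume_fraction: list[float] = field(default_factory=list)
    compliance_Nmm: list[float] = field(default_factory=list)
    density_history: list[np.ndarray] = field(default_factory=list)
    initial_compliance_Nmm: float = float("nan")
    converged: list[bool] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.volume_fraction)

    @property
    def final_volume_fraction(self) -> float:
        return self.volume_fraction[-1]


def compliance_and_sensitivity(
    domain: DesignDomain,
    material: fem.Material,
    load_case: fem.LoadCase,
    penalty_p: float = 3.0,
    *,
    method: str = "auto",
    u0: np.ndarray | None = None,
) -> tuple[float, np.ndarray, fem.DisplacementField]:
    """Compliance C = f.u and its density gradient dC/drho per voxel.

    With K_e = [E_min + rho^p (E0 - E_min)] k0, the adjoint gradient is
    dC/drho_e = -p rho^(p-1) (1 - E_min/E0) u_e^T k0 u_e <= 0: removing
    material can never reduce compliance.  Returns the displacement field so
    callers can warm-start subsequent solves.
    """
    u = fem.solve(domain, material, load_case, penalty_p, method=method, u0=u0)
    KE = fem.element_stiffness(material, domain.voxel_size)
    edof = fem.edof_matrix(domain.resolution)
    ue = u.values.ravel()[edof]
    q = np.einsum("ij,jk,ik->i", ue, KE, ue)  # u_e^T k0 u_e per voxel
    rho = domain.density.ravel()
    sens = -penalty_p * np.maximum(rho, 0.0) ** (penalty_p - 1) * (1.0 - fem.E_MIN_RATIO) * q
    sens[domain.void_mask.ravel()] = 0.0
    return u.compliance_Nmm, sens.reshape(domain.resolution), u


def _filter_matrix(domain: DesignDomain, radius_mm: float) -> sp.csr_matrix | None:
    """Row-normalised linear-decay smoothing weights over solid voxel centres."""
    h = domain.voxel_size
    if radius_mm < min(h):
        return None
    cx, cy, cz = domain.centres()
    solid = np.nonzero(domain.solid_mask.ravel())[0]
    ii, jj, kk = np.unravel_index(solid, domain.resolution)
    pts = np.column_stack([cx[ii], cy[jj], cz[kk]])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_mm, output_type="ndarray")
    n = len(solid)
    di = np.concatenate([np.arange(n), pairs[:, 0], pairs[:, 1]])
    dj = np.concatenate([np.arange(n), pairs[:, 1], pairs[:, 0]])
    dist = np.linalg.norm(pts[di] - pts[dj], axis=1)
    w = radius_mm - dist
    H = sp.coo_matrix((w, (di, dj)), shape=(n, n)).tocsr()
    rowsum = np.asarray(H.sum(axis=1)).ravel()
    H = sp.diags(1.0 / rowsum) @ H
    return H


def filter_sensitivities(
    sens: np.ndarray, domain: DesignDomain, radius_mm: float,
    H: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Mesh-independency filter: convex combination of neighbouring sensitivities.

    Weights decay linearly to zero at ``radius_mm``; a spatially constant
    field passes through unchanged, and radii below one voxel edge reduce to
    the identity.  ``H`` allows reuse of a precomputed weight matrix.
    """
    if H is None:
        H = _filter_matrix(domain, radius_mm)
    if H is None:
        return sens.copy()
    out = np.zeros_like(sens)
    solid = domain.solid_mask.ravel()
    out.ravel()[solid] = H @ sens.ravel()[solid]
    return out


def update_densities(
    domain: DesignDomain,
    sens: np.ndarray,
    volume_target: float,
    *,
    move: float = OC_MOVE,
    damping: float = OC_DAMPING,
) -> DesignDomain:
    """Optimality-criteria density update towards a volume-fraction target.

    Bisection on the Lagrange multiplier of the volume constraint; densities
    stay in [RHO_MIN, 1] with a move limit per update, void voxels stay
    empty, frozen voxels stay full, and the mid-sagittal mirror symmetry is
    re-imposed exactly afterwards.
    """
    design = domain.design_mask
    n_solid = int(domain.solid_mask.sum())
    n_frozen = int((domain.frozen_mask & domain.solid_mask).sum())
    target_sum = volume_target * n_solid - 1.0 * n_frozen
    if target_sum < 0:
        raise ValueError(
            f"volume target {volume_target} infeasible: frozen structure alone "
            f"occupies {n_frozen / n_solid:.3f} of the solid volume"
        )
    x = domain.density[design]
    b = np.maximum(-sens[design], 0.0)

    lo = np.maximum(x - move, RHO_MIN)
    hi = np.minimum(x + move, 1.0)

    def candidate(lam: float) -> np.ndarray:
        return np.clip(x * (b / lam) ** damping, lo, hi)

    if target_sum < lo.sum() - 1e-9 * n_solid:
        raise ValueError("volume target unreachable within move limits")

    l1, l2 = 1e-30, 1e30
    xnew = x
    for _ in range(200):
        lam = np.sqrt(l1 * l2)
        xnew = candidate(lam)
        if xnew.sum() > target_sum:
            l1 = lam
        else:
            l2 = lam
        if (l2 - l1) / (l1 + l2) < OC_BISECT_TOL:
            break

    out = domain.copy()
    out.density[design] = xnew
    if domain.symmetric:
        out.symmetrise()
    return out


def _symmetric_half(domain: DesignDomain, load_case: fem.LoadCase):
    """Half-width model equivalent to the full laterally symmetric problem.

    Returns ``(half_domain, half_load_case)`` when the geometry, masks and
    loads are all mirror-symmetric about the mid-sagittal plane and the
    lateral voxel count is even; otherwise None.  The mid-plane becomes the
    half model's lateral_right face with the lateral displacement locked,
    and face tractions carry half the total force (same traction intensity).
    """
    from dataclasses import replace as _replace

    nx, ny, nz = domain.resolution
    if not domain.symmetric or ny % 2:
        return None
    if load_case.line_loads or load_case.fixed_dof_ids:
        return None
    if not (
        np.array_equal(domain.void_mask, domain.mirrored(domain.void_mask))
        and np.array_equal(domain.frozen_mask, domain.mirrored(domain.frozen_mask))
        and np.allclose(domain.density, domain.mirrored(domain.density))
    ):
        return None
    for t in load_case.tractions:
        if t.face in ("lateral_left", "lateral_right") or t.force_N[1] != 0:
            return None
    for face in load_case.fixed_faces:
        if face in ("lateral_left", "lateral_right"):
            return None
    h = ny // 2
    params = _replace(domain.params, width_mm=domain.params.width_mm / 2,
                      n_rows=0, holes_per_row=0)
    half = DesignDomain(
        params=params,
        resolution=(nx, h, nz),
        density=domain.density[:, :h, :].copy(),
        void_mask=domain.void_mask[:, :h, :].copy(),
        frozen_mask=domain.frozen_mask[:, :h, :].copy(),
        symmetric=False,
    )
    fixed = dict(load_case.fixed_faces)
    fixed["lateral_right"] = (False, True, False)  # mirror plane: u_y = 0
    tr = tuple(
        fem.FaceTraction(t.face, (t.force_N[0] / 2, 0.0, t.force_N[2] / 2))
        for t in load_case.tractions
    )
    return half, fem.LoadCase(fixed_faces=fixed, tractions=tr)


def optimise(
    domain: DesignDomain,
    material: fem.Material,
    load_case: fem.LoadCase,
    schedule: OptimisationSchedule = OptimisationSchedule(),
    *,
    penalty_p: float = 3.0,
    filter_radius_voxels: float = 1.5,
    freeze_ventral: bool = True,
    method: str = "auto",
    use_symmetry: bool = True,
    keep_history: bool = True,
    callback=None,
) -> OptimisationResult:
    """Run the stepped compliance-minimising optimisation.

    Each stage lowers the volume-fraction target by one step and iterates the
    OC update until the maximum density change drops below the convergence
    tolerance (or ``inner_iters_max`` is reached, in which case a warning is
    emitted and the best iterate is kept).  Within a stage the OC move limit
    is annealed (halved every few iterations) to quench the flip-flopping of
    low-sensitivity voxels between their bounds.  When the problem is
    laterally symmetric, the state equation is solved on a half-width model
    (mirror-plane boundary condition) and sensitivities are mirrored back.
    The recorded per-stage compliance is evaluated on the converged density
    field of that stage.
    """
    dom = domain.copy()
    if freeze_ventral:
        dom.freeze_face_layer("ventral")
    radius_mm = filter_radius_voxels * min(dom.voxel_size)
    H = _filter_matrix(dom, radius_mm)

    sym = _symmetric_half(dom, load_case) if use_symmetry else None
    half_state = {"u": None}

    def solve_cs(d: DesignDomain):
        if sym is None:
            c, s, u = compliance_and_sensitivity(
                d, material, load_case, penalty_p, method=method,
                u0=half_state["u"],
            )
            half_state["u"] = u.values
            return c, s, u
        half_dom, half_lc = sym
        half_dom.density = d.density[:, : d.resolution[1] // 2, :]
        c_h, s_h, u_h = compliance_and_sensitivity(
            half_dom, material, half_lc, penalty_p, method=method,
            u0=half_state["u"],
        )
        half_state["u"] = u_h.values
        return 2.0 * c_h, np.concatenate([s_h, s_h[:, ::-1, :]], axis=1), u_h

    result = OptimisationResult(domain=dom)
    c, sens, u = solve_cs(dom)
    result.initial_compliance_Nmm = c

    for stage, target in enumerate(schedule.targets(), start=1):
        converged = False
        for it in range(schedule.inner_iters_max):
            move = max(OC_MOVE * 0.5 ** (it // 3), 0.5 * schedule.convergence_tol)
            sens_f = filter_sensitivities(sens, dom, radius_mm, H=H)
            new_dom = update_densities(dom, sens_f, target, move=move)
            change = float(np.abs(new_dom.density - dom.density).max())
            dom = new_dom
            c, sens, u = solve_cs(dom)
            if change < schedule.convergence_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"stage {stage}: OC iteration hit inner_iters_max="
                f"{schedule.inner_iters_max} (last density change {change:.4f}); "
                "proceeding with the final iterate",
                stacklevel=2,
            )
        vf = dom.volume_fraction()
        result.volume_fraction.append(vf)
        result.compliance_Nmm.append(c)
        result.converged.append(converged)
        if keep_history:
            result.density_history.append(dom.density.copy())
        log.info("stage %d: volume fraction %.4f, compliance %.6g N mm", stage, vf, c)
        if callback is not None:
            callback(stage, dom, c)

    result.domain = dom
    return result
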