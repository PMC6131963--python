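"""Small-strain isotropic linear elasticity on the voxel hexahedral grid.

Eight-node trilinear hexahedra with 2x2x2 Gauss integration on a regular
grid; element stiffness is modulated by the voxel density through the SIMP
interpolation E(rho) = E_min + rho^p (E0 - E_min) with a small stiffness
floor that keeps the constrained system nonsingular while voxels empty.
Units are mm-N-MPa, so displacements come out in mm and stresses in MPa.

The solver is a direct sparse factorisation at desk resolutions, with a
Jacobi-preconditioned conjugate-gradient fallback for larger systems; both
honour the same relative-residual contract (<= 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DesignDomain

__all__ = [
    "Material",
    "FaceTraction",
    "LineLoad",
    "LoadCase",
    "DisplacementField",
    "StressField",
    "SolverError",
    "element_stiffness",
    "assemble",
    "solve",
    "recover_stress",
]

E_MIN_RATIO = 1e-9  # stiffness floor as a fraction of E0

# local node order of the hexahedron (offsets within a voxel)
NODE_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
)
_XI = 2.0 * NODE_OFFSETS - 1.0  # natural coordinates of the nodes


class SolverError(RuntimeError):
    """Raised when the linear system is singular or the solver fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (collagen-like defaults).

    The published pad model uses E = sigma_t = 20 MPa and nu = 0.33, within
    the range reported for collagenous tissues.
    """

    E_MPa: float = 20.0
    nu: float = 0.33
    sigma_t_MPa: float = 20.0

    def __post_init__(self) -> None:
        if self.E_MPa <= 0:
            raise ValueError("E_MPa must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")

    def elasticity_matrix(self) -> np.ndarray:
        """6x6 isotropic Hooke matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self.E_MPa, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] = lam + 2 * mu
        D[3:, 3:] = np.eye(3) * mu
        return D


@dataclass(frozen=True)
class FaceTraction:
    """Total force (N) spread uniformly over the solid voxel faces of a boundary face."""

    face: str
    force_N: tuple[float, float, float]


@dataclass(frozen=True)
class LineLoad:
    """Total force (N) spread equally over an explicit set of node indices."""

    node_ids: tuple[int, ...]
    force_N: tuple[float, float, float]
    label: str = ""


@dataclass(frozen=True)
class LoadCase:
    """Boundary conditions: per-face displacement locks plus applied loads.

    ``fixed_faces`` maps a face name to a per-axis lock triple; the default
    clamps the ventral face completely (displacement of the ventral model
    surface prohibited).
    """

    fixed_faces: dict[str, tuple[bool, bool, bool]] = field(
        default_factory=lambda: {"ventral": (True, True, True)}
    )
    tractions: tuple[FaceTraction, ...] = ()
    line_loads: tuple[LineLoad, ...] = ()
    fixed_dof_ids: tuple[int, ...] = ()  # explicit extra DOF locks (patch tests)

    def __post_init__(self) -> None:
        for t in self.tractions:
            locks = self.fixed_faces.get(t.face)
            if locks is not None and all(locks):
                raise ValueError(f"traction applied on fully fixed face {t.face!r}")

    @property
    def total_force_N(self) -> np.ndarray:
        tot = np.zeros(3)
        for t in self.tractions:
            tot += np.asarray(t.force_N)
        for l in self.line_loads:
            tot += np.asarray(l.force_N)
        return tot


# ---------------------------------------------------------------------------
# element matrices and grid indexing
# ---------------------------------------------------------------------------

def _shape_gradients(xi: float, eta: float, zeta: float,
                     h: tuple[float, float, float]) -> np.ndarray:
    """(8, 3) physical gradients dN/dx at a natural-coordinate point."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _XI[a]
        g[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta) * 2.0 / h[0]
        g[a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta) * 2.0 / h[1]
        g[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta) * 2.0 / h[2]
    return g


def strain_displacement(xi: float, eta: float, zeta: float,
                        h: tuple[float, float, float]) -> np.ndarray:
    """6x24 B matrix (Voigt order xx, yy, zz, xy, yz, zx) at a natural point."""
    g = _shape_gradients(xi, eta, zeta, h)
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c] = g[a, 0]
        B[1, c + 1] = g[a, 1]
        B[2, c + 2] = g[a, 2]
        B[3, c] = g[a, 1]
        B[3, c + 1] = g[a, 0]
        B[4, c + 1] = g[a, 2]
        B[4, c + 2] = g[a, 1]
        B[5, c] = g[a, 2]
        B[5, c + 2] = g[a, 0]
    return B


@lru_cache(maxsize=32)
def _element_stiffness_cached(E: float, nu: float, hx: float, hy: float, hz: float) -> np.ndarray:
    D = Material(E_MPa=E, nu=nu).elasticity_matrix()
    gp = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))
    detJ = hx * hy * hz / 8.0
    KE = np.zeros((24, 24))
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                B = strain_displacement(xi, eta, zeta, (hx, hy, hz))
                KE += B.T @ D @ B * detJ
    return KE


def element_stiffness(material: Material, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """24x24 stiffness matrix of a full-density rectangular hexahedron."""
    hx, hy, hz = voxel_size
    return _element_stiffness_cached(material.E_MPa, material.nu, hx, hy, hz)


def node_count(resolution: tuple[int, int, int]) -> int:
    nx, ny, nz = resolution
    return (nx + 1) * (ny + 1) * (nz + 1)


def node_index(resolution: tuple[int, int, int],
               ix: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
    nx, ny, nz = resolution
    return (np.asarray(ix) * (ny + 1) + np.asarray(iy)) * (nz + 1) + np.asarray(iz)


@lru_cache(maxsize=8)
def _edof_cached(resolution: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = resolution
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    nodes = np.stack(
        [node_index(resolution, ii + a, jj + b, kk + c) for a, b, c in NODE_OFFSETS],
        axis=1,
    )  # (n_voxels, 8)
    edof = np.empty((len(ii), 24), dtype=np.int64)
    edof[:, 0::3] = 3 * nodes
    edof[:, 1::3] = 3 * nodes + 1
    edof[:, 2::3] = 3 * nodes + 2
    edof.setflags(write=False)
    return edof


def edof_matrix(resolution: tuple[int, int, int]) -> np.ndarray:
    """(n_voxels, 24) DOF indices per voxel, voxels flattened in C order [ix, iy, iz]."""
    return _edof_cached(tuple(int(n) for n in resolution))


def stiffness_factors(domain: DesignDomain, penalty_p: float) -> np.ndarray:
    """Per-voxel SIMP stiffness scale in [E_min/E0, 1]; zero on void voxels."""
    rho = domain.density
    fac = E_MIN_RATIO + rho**penalty_p * (1.0 - E_MIN_RATIO)
    fac = np.where(domain.void_mask, 0.0, fac)
    return fac.ravel()


# ---------------------------------------------------------------------------
# boundary conditions and loads
# ---------------------------------------------------------------------------

def face_nodes(resolution: tuple[int, int, int], face: str) -> np.ndarray:
    """Node indices lying on a named boundary face of the grid."""
    nx, ny, nz = resolution
    ax_ix = np.arange(nx + 1)
    ax_iy = np.arange(ny + 1)
    ax_iz = np.arange(nz + 1)
    sel = {
        "ventral": (ax_ix, ax_iy, np.array([0])),
        "dorsal": (ax_ix, ax_iy, np.array([nz])),
        "proximal": (np.array([0]), ax_iy, ax_iz),
        "distal": (np.array([nx]), ax_iy, ax_iz),
        "lateral_left": (ax_ix, np.array([0]), ax_iz),
        "lateral_right": (ax_ix, np.array([ny]), ax_iz),
    }
    if face not in sel:
        raise ValueError(f"unknown face {face!r}")
    ix, iy, iz = np.meshgrid(*sel[face], indexing="ij")
    return node_index(resolution, ix.ravel(), iy.ravel(), iz.ravel())


def fixed_dofs(domain: DesignDomain, load_case: LoadCase) -> np.ndarray:
    """Sorted DOF indices locked by the load case's fixed faces."""
    res = domain.resolution
    dofs: list[np.ndarray] = []
    for face, locks in load_case.fixed_faces.items():
        nodes = face_nodes(res, face)
        for axis, locked in enumerate(locks):
            if locked:
                dofs.append(3 * nodes + axis)
    if load_case.fixed_dof_ids:
        dofs.append(np.asarray(load_case.fixed_dof_ids, dtype=np.int64))
    if not dofs:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(dofs))


def _boundary_face_quads(domain: DesignDomain, face: str) -> np.ndarray:
    """(n_faces, 4) node indices of solid voxel faces on a boundary face."""
    res = domain.resolution
    nx, ny, nz = res
    solid = domain.solid_mask
    if face in ("proximal", "distal"):
        i = 0 if face == "proximal" else nx - 1
        jj, kk = np.nonzero(solid[i])
        ii = np.full_like(jj, i if face == "proximal" else nx)
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        quads = np.stack(
            [node_index(res, ii, jj + a, kk + b) for a, b in corners], axis=1
        )
    elif face in ("ventral", "dorsal"):
        k = 0 if face == "ventral" else nz - 1
        ii, jj = np.nonzero(solid[:, :, k])
        kk = np.full_like(ii, k if face == "ventral" else nz)
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        quads = np.stack(
            [node_index(res, ii + a, jj + b, kk) for a, b in corners], axis=1
        )
    else:
        j = 0 if face == "lateral_left" else ny - 1
        ii, kk = np.nonzero(solid[:, j, :])
        jj = np.full_like(ii, j if face == "lateral_left" else ny)
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        quads = np.stack(
            [node_index(res, ii + a, jj, kk + b) for a, b in corners], axis=1
        )
    return quads


def load_vector(domain: DesignDomain, load_case: LoadCase) -> np.ndarray:
    """Assemble the global nodal force vector (N).

    Face tractions are spread uniformly over the solid voxel faces of the
    named boundary face (a quarter of each face's share per corner node), so
    the nodal sum equals the requested total force exactly.
    """
    ndof = 3 * node_count(domain.resolution)
    f = np.zeros(ndof)
    for t in load_case.tractions:
        quads = _boundary_face_quads(domain, t.face)
        if quads.size == 0:
            raise ValueError(f"no solid voxel faces on face {t.face!r} to load")
        share = np.asarray(t.force_N) / (4.0 * len(quads))
        for axis in range(3):
            if share[axis] != 0.0:
                np.add.at(f, 3 * quads.ravel() + axis, share[axis])
    for l in load_case.line_loads:
        nodes = np.asarray(l.node_ids, dtype=np.int64)
        if nodes.size == 0:
            raise ValueError("line load with no nodes")
        share = np.asarray(l.force_N) / len(nodes)
        for axis in range(3):
            if share[axis] != 0.0:
                np.add.at(f, 3 * nodes + axis, share[axis])
    return f


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------

def assemble(domain: DesignDomain, material: Material, penalty_p: float = 3.0) -> sp.csc_matrix:
    """Global stiffness matrix over non-void voxels (unconstrained, symmetric)."""
    if not domain.solid_mask.any():
        raise SolverError("fully void domain: nothing to assemble")
    KE = element_stiffness(material, domain.voxel_size)
    edof = edof_matrix(domain.resolution)
    fac = stiffness_factors(domain, penalty_p)
    keep = fac > 0.0
    edof = edof[keep]
    fac = fac[keep]
    ndof = 3 * node_count(domain.resolution)
    iK = np.repeat(edof, 24, axis=1).ravel()
    jK = np.tile(edof, (1, 24)).ravel()
    sK = (fac[:, None] * KE.ravel()[None, :]).ravel()
    K = sp.coo_matrix((sK, (iK, jK)), shape=(ndof, ndof)).tocsc()
    K.sum_duplicates()
    return K


@dataclass
class DisplacementField:
    """Nodal solution of a load case on a voxel domain.

    ``values`` is (n_nodes, 3) in mm; ``reactions`` holds the constraint
    forces (N), nonzero only on fixed DOFs; ``compliance_Nmm`` is the work
    of the applied loads f.u.
    """

    domain: DesignDomain
    values: np.ndarray
    reactions: np.ndarray
    load: np.ndarray
    fixed: np.ndarray
    residual: float

    @property
    def compliance_Nmm(self) -> float:
        return float(self.load @ self.values.ravel())

    def reaction_sum(self) -> np.ndarray:
        """Net reaction force vector (N); balances -(applied load)."""
        return self.reactions.reshape(-1, 3).sum(axis=0)

    def node_coords(self) -> np.ndarray:
        nx, ny, nz = self.domain.resolution
        hx, hy, hz = self.domain.voxel_size
        ix, iy, iz = np.meshgrid(
            np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
        )
        return np.column_stack([(ix.ravel() * hx), (iy.ravel() * hy), (iz.ravel() * hz)])


def solve(
    domain: DesignDomain,
    material: Material,
    load_case: LoadCase,
    penalty_p: float = 3.0,
    *,
    method: str = "auto",
    rtol: float = 1e-8,
    u0: np.ndarray | None = None,
) -> DisplacementField:
    """Solve the constrained elasticity system for a load case.

    ``method`` is "direct" (sparse LU), "cg" (Jacobi-preconditioned CG,
    optionally warm-started from ``u0``), or "auto" (direct below ~2e5 free
    DOFs).  The relative residual on the free DOFs is checked against
    ``rtol`` either way.
    """
    K = assemble(domain, material, penalty_p)
    f = load_vector(domain, load_case)
    fixed = fixed_dofs(domain, load_case)
    ndof = K.shape[0]

    # DOFs with (numerically) no stiffness: nodes not attached to any
    # non-void element; constrain them so the reduced system is definite.
    attached = np.asarray(K.getnnz(axis=0) > 0)
    dangling = np.nonzero(~attached)[0]
    fixed_all = np.unique(np.concatenate([fixed, dangling]))
    if fixed.size == 0:
        raise SolverError(
            "no fixed face: the system has unconstrained rigid-body modes"
        )
    free = np.setdiff1d(np.arange(ndof), fixed_all, assume_unique=False)

    Kff = K[free][:, free]
    ff = f[free]
    fnorm = np.linalg.norm(ff)
    if method == "auto":
        method = "direct" if free.size <= 200_000 else "cg"

    if method == "direct":
        try:
            lu = spla.splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A",
                           options=dict(SymmetricMode=True))
            uf = lu.solve(ff)
        except RuntimeError as exc:  # singular factorisation
            raise SolverError(f"direct solve failed: {exc}") from exc
    elif method == "cg":
        M = sp.diags(1.0 / Kff.diagonal())
        x0 = u0.ravel()[free] if u0 is not None else None
        uf, info = spla.cg(Kff, ff, x0=x0, M=M, rtol=rtol * 1e-2, maxiter=20_000)
        if info != 0:
            res = np.linalg.norm(Kff @ uf - ff) / max(fnorm, 1e-300)
            raise SolverError(f"CG did not converge (info={info})", residual=res)
    else:
        raise ValueError(f"unknown solver method {method!r}")

    res = np.linalg.norm(Kff @ uf - ff) / max(fnorm, 1e-300)
    if fnorm > 0 and res > rtol:
        raise SolverError("solver residual above tolerance", residual=res)

    u = np.zeros(ndof)
    u[free] = uf
    r = np.zeros(ndof)
    r[fixed_all] = (K @ u - f)[fixed_all]
    return DisplacementField(
        domain=domain,
        values=u.reshape(-1, 3),
        reactions=r.reshape(-1, 3).reshape(-1, 3),
        load=f,
        fixed=fixed_all,
        residual=float(res),
    )


# ---------------------------------------------------------------------------
# stress recovery
# ---------------------------------------------------------------------------

@dataclass
class StressField:
    """Element-centroid stress tensors (MPa) with derived invariants.

    ``tensors`` is (nx, ny, nz, 3, 3); void voxels carry zeros and are
    excluded via ``mask``.  Principal values are sorted descending
    (sigma1 >= sigma2 >= sigma3, tension positive) with orthonormal
    direction triads.
    """

    domain: DesignDomain
    tensors: np.ndarray
    mask: np.ndarray

    _vm: np.ndarray | None = None
    _pvals: np.ndarray | None = None
    _pdirs: np.ndarray | None = None

    @property
    def von_mises(self) -> np.ndarray:
        if self._vm is None:
            s = self.tensors
            sxx, syy, szz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
            sxy, syz, szx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
            self._vm = np.sqrt(
                0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                + 3.0 * (sxy**2 + syz**2 + szx**2)
            )
        return self._vm

    def _decompose(self) -> None:
        shape = self.tensors.shape[:3]
        flat = self.tensors.reshape(-1, 3, 3)
        w, v = np.linalg.eigh(flat)  # ascending
        self._pvals = w[:, ::-1].reshape(*shape, 3)
        self._pdirs = v[:, :, ::-1].reshape(*shape, 3, 3)

    @property
    def principal_values(self) -> np.ndarray:
        if self._pvals is None:
            self._decompose()
        return self._pvals

    @property
    def principal_directions(self) -> np.ndarray:
        """(..., 3, 3); column ``[..., :, i]`` is the direction of sigma_(i+1)."""
        if self._pdirs is None:
            self._decompose()
        return self._pdirs


def recover_stress(
    domain: DesignDomain,
    material: Material,
    u: DisplacementField,
    penalty_p: float = 3.0,
) -> StressField:
    """Element-centroid stresses from the strain-displacement operator and Hooke's law.

    The Hooke matrix of each element is scaled by its SIMP stiffness factor,
    so stresses are consistent with the stiffness actually assembled.
    """
    res = domain.resolution
    B0 = strain_displacement(0.0, 0.0, 0.0, domain.voxel_size)
    D = material.elasticity_matrix()
    edof = edof_matrix(res)
    fac = stiffness_factors(domain, penalty_p)
    ue = u.values.ravel()[edof]  # (n_voxels, 24)
    sig_voigt = (ue @ B0.T) @ D.T * fac[:, None]  # (n_voxels, 6)
    t = np.zeros((len(edof), 3, 3))
    t[:, 0, 0] = sig_voigt[:, 0]
    t[:, 1, 1] = sig_voigt[:, 1]
    t[:, 2, 2] = sig_voigt[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = sig_voigt[:, 3]
    t[:, 1, 2] = t[:, 2, 1] = sig_voigt[:, 4]
    t[:, 0, 2] = t[:, 2, 0] = sig_voigt[:, 5]
    return StressField(
        domain=domain,
        tensors=t.reshape(*res, 3, 3),
        mask=domain.solid_mask.copy(),
    )
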