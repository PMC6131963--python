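"""Post-processing of solved stress fields into reported loading patterns.

Three analyses mirror how the pad model's mechanics are read:

* maximum-principal-stress trajectories - streamlines of the eigenvector
  field of the largest stress eigenvalue, visualising the paths along which
  the shear load is carried from the proximal face to the ventral surface;
* von Mises contrasts - the inter-row vs intra-row webbing comparison around
  the duct holes plus the proximal-to-distal stress decay by quartile;
* ridge profile - the lateral density profile of an optimised field in the
  duct region, locating the troughs (aligned with the hole rows) and the
  ridges between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fem import StressField
from .geometry import DesignDomain

__all__ = [
    "Trajectory",
    "trace_trajectories",
    "ContrastReport",
    "von_mises_contrasts",
    "RidgeProfile",
    "ridge_profile",
    "default_proximal_seeds",
]

_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


@dataclass
class Trajectory:
    """An integrated maximum-principal-direction streamline."""

    points: np.ndarray  # (n, 3) mm
    seed: np.ndarray
    termination: str  # left_domain | entered_void | max_steps

    @property
    def max_x(self) -> float:
        return float(self.points[:, 0].max())

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]


def _material_lookup(domain: DesignDomain, threshold: float = 0.5):
    """Point -> material presence (solid voxel with density above threshold)."""
    nx, ny, nz = domain.resolution
    hx, hy, hz = domain.voxel_size
    present = domain.solid_mask & (domain.density >= threshold)

    def inside(p: np.ndarray) -> tuple[bool, bool]:
        """(in bounding box, in material)."""
        i = int(np.floor(p[0] / hx))
        j = int(np.floor(p[1] / hy))
        k = int(np.floor(p[2] / hz))
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            return False, False
        return True, bool(present[i, j, k])

    return inside


def _tensor_interpolator(stress: StressField):
    """Trilinear interpolation of the six stress components at centroid grid points."""
    domain = stress.domain
    cx, cy, cz = domain.centres()
    comps = np.stack([stress.tensors[..., a, b] for a, b in _VOIGT], axis=-1)
    interp = RegularGridInterpolator(
        (cx, cy, cz), comps, method="linear", bounds_error=False, fill_value=None
    )

    def tensor_at(p: np.ndarray) -> np.ndarray:
        v = interp(p[None, :])[0]
        t = np.empty((3, 3))
        t[0, 0], t[1, 1], t[2, 2] = v[0], v[1], v[2]
        t[0, 1] = t[1, 0] = v[3]
        t[1, 2] = t[2, 1] = v[4]
        t[0, 2] = t[2, 0] = v[5]
        return t

    return tensor_at


def default_proximal_seeds(domain: DesignDomain, n_per_axis: int = 5) -> np.ndarray:
    """Regular seed grid just inside the solid part of the loaded proximal face.

    The dorsoproximal recess truncates the proximal face, so the seed grid
    spans only the dorsoventral range over which the face is solid across
    the full width (this is also where the shear load is applied).
    """
    hx, _, hz = domain.voxel_size
    p = domain.params
    solid_cols = domain.solid_mask[0].all(axis=0)  # z-levels solid for every y
    k_top = int(np.nonzero(solid_cols)[0].max()) if solid_cols.any() else 0
    z_max = (k_top + 1) * hz
    ys = np.linspace(0, p.width_mm, n_per_axis + 2)[1:-1]
    zs = np.linspace(0, z_max, n_per_axis + 2)[1:-1]
    yy, zz = np.meshgrid(ys, zs)
    x0 = 0.51 * hx  # first centroid layer, marginally inside
    return np.column_stack([np.full(yy.size, x0), yy.ravel(), zz.ravel()])


def trace_trajectories(
    stress: StressField,
    domain: DesignDomain,
    seeds: np.ndarray | None = None,
    step_mm: float | None = None,
    *,
    max_steps: int = 4000,
    density_threshold: float = 0.5,
) -> list[Trajectory]:
    """Integrate streamlines of the unit maximum-principal-direction field.

    Fixed-step RK4 on the interpolated stress tensor (interpolate the tensor,
    then eigen-decompose) with sign continuity: the eigenvector is flipped
    whenever it reverses relative to the previous step, so the trajectories
    are invariant to the global sign convention of the field.  The initial
    direction is taken pointing into the domain (+x).  Integration stops on
    leaving the bounding box, on entering void or sub-threshold material, or
    after ``max_steps``.
    """
    if seeds is None:
        seeds = default_proximal_seeds(domain)
    if step_mm is None:
        step_mm = 0.5 * min(domain.voxel_size)
    tensor_at = _tensor_interpolator(stress)
    inside = _material_lookup(domain, density_threshold)

    def direction(p: np.ndarray, prev: np.ndarray) -> np.ndarray:
        t = tensor_at(p)
        w, v = np.linalg.eigh(t)
        d = v[:, -1]
        if d @ prev < 0:
            d = -d
        return d

    out: list[Trajectory] = []
    for seed in np.atleast_2d(seeds):
        in_box, in_mat = inside(seed)
        if not (in_box and in_mat):
            warnings.warn(f"seed {seed} lies in void; skipped", stacklevel=2)
            continue
        p = seed.astype(float).copy()
        prev = np.array([1.0, 0.0, 0.0])  # start pointing distally into the domain
        pts = [p.copy()]
        termination = "max_steps"
        for _ in range(max_steps):
            k1 = direction(p, prev)
            k2 = direction(p + 0.5 * step_mm * k1, k1)
            k3 = direction(p + 0.5 * step_mm * k2, k2)
            k4 = direction(p + step_mm * k3, k3)
            d = k1 + 2 * k2 + 2 * k3 + k4
            d /= np.linalg.norm(d)
            p = p + step_mm * d
            in_box, in_mat = inside(p)
            if not in_box:
                termination = "left_domain"
                break
            pts.append(p.copy())
            if not in_mat:
                termination = "entered_void"
                break
            prev = d
        out.append(Trajectory(points=np.array(pts), seed=seed.copy(), termination=termination))
    return out


# ---------------------------------------------------------------------------
# von Mises contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastReport:
    """Webbing and longitudinal von Mises comparisons of a solved model.

    ``inter_row_mean`` averages over solid voxels of the duct band whose
    lateral ordinate lies between adjacent hole-row centrelines (beyond a
    hole radius of both); ``intra_row_mean`` over solid voxels within a hole
    radius of a row centreline (the webs between consecutive holes of a
    row).  ``quartile_means`` are proximal-to-distal means over four equal
    longitudinal bins of the whole domain.
    """

    inter_row_mean: float
    intra_row_mean: float
    ratio: float
    quartile_means: np.ndarray
    n_inter: int
    n_intra: int
    holes_defined: bool


def von_mises_contrasts(stress: StressField, domain: DesignDomain) -> ContrastReport:
    """Webbing stress ratio and longitudinal decay of the von Mises field."""
    p = domain.params
    vm = stress.von_mises
    solid = domain.solid_mask
    cx, cy, cz = domain.centres()

    xq = np.clip((cx / p.length_mm * 4).astype(int), 0, 3)
    quart = np.empty(4)
    for q in range(4):
        m = solid & (xq == q)[:, None, None]
        quart[q] = vm[m].mean() if m.any() else np.nan

    if p.n_holes == 0:
        return ContrastReport(np.nan, np.nan, np.nan, quart, 0, 0, holes_defined=False)

    x_lo, x_hi = p.hole_field_span_x()
    in_band = (cx >= x_lo) & (cx <= x_hi)
    rows = p.row_ordinates()
    r = 0.5 * p.hole_diameter_mm
    dist = np.abs(cy[:, None] - rows[None, :])  # (ny, n_rows)
    intra_y = (dist <= r).any(axis=1)
    between = np.zeros(len(cy), dtype=bool)
    for y0, y1 in zip(rows[:-1], rows[1:]):
        between |= (cy > y0) & (cy < y1)
    inter_y = between & (dist > r).all(axis=1)

    band3 = in_band[:, None, None] & np.ones_like(solid, dtype=bool)
    inter_mask = solid & band3 & inter_y[None, :, None]
    intra_mask = solid & band3 & intra_y[None, :, None]
    inter_mean = float(vm[inter_mask].mean()) if inter_mask.any() else np.nan
    intra_mean = float(vm[intra_mask].mean()) if intra_mask.any() else np.nan
    return ContrastReport(
        inter_row_mean=inter_mean,
        intra_row_mean=intra_mean,
        ratio=inter_mean / intra_mean,
        quartile_means=quart,
        n_inter=int(inter_mask.sum()),
        n_intra=int(intra_mask.sum()),
        holes_defined=True,
    )


# ---------------------------------------------------------------------------
# ridge profile
# ---------------------------------------------------------------------------

@dataclass
class RidgeProfile:
    """Lateral density profile of the duct band with its extrema."""

    y_mm: np.ndarray  # lateral voxel-column ordinates
    profile: np.ndarray  # band-averaged density per ordinate
    trough_y: np.ndarray  # local minima positions (mm)
    ridge_y: np.ndarray  # local maxima positions (mm)


def _plateau_extrema(y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima/maxima positions, plateaus reported at their centre."""
    n = len(v)
    # compress runs of equal values
    starts = [0]
    for i in range(1, n):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    runs = [(s, (starts[k + 1] - 1) if k + 1 < len(starts) else n - 1)
            for k, s in enumerate(starts)]
    mins, maxs = [], []
    for k in range(1, len(runs) - 1):
        s, e = runs[k]
        left = v[runs[k - 1][1]]
        right = v[runs[k + 1][0]]
        centre = 0.5 * (y[s] + y[e])
        if v[s] < left and v[s] < right:
            mins.append(centre)
        elif v[s] > left and v[s] > right:
            maxs.append(centre)
    return np.array(mins), np.array(maxs)


def ridge_profile(
    domain: DesignDomain,
    duct_band: tuple[float, float] | None = None,
) -> RidgeProfile:
    """Average the density over the duct band per lateral ordinate and find extrema.

    The duct band defaults to the longitudinal interval spanned by the hole
    field (full height).  Troughs of the optimised field are expected in
    line with the hole rows, ridges between and outside them.
    """
    p = domain.params
    if duct_band is None:
        if p.n_holes == 0:
            duct_band = (0.0, p.length_mm)
        else:
            duct_band = p.hole_field_span_x()
    cx, cy, _ = domain.centres()
    in_band = (cx >= duct_band[0]) & (cx <= duct_band[1])
    sub = domain.density[in_band, :, :]
    profile = sub.mean(axis=(0, 2))
    trough_y, ridge_y = _plateau_extrema(cy, profile)
    return RidgeProfile(y_mm=cy, profile=profile, trough_y=trough_y, ridge_y=ridge_y)
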