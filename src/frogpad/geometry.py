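"""Parametric geometry of the ventral collagen-layer pad model.

The ventral collagen layer of a tree-frog digital pad is idealised as a
rectangular box (proximal->distal x, lateral y, ventral->dorsal z; ventral
face at z = 0) pierced by vertical cylindrical holes that stand in for the
mucus ducts, with an optional quarter-cylinder recess at the dorsoproximal
edge representing the neighbouring proximal epiphysis of the distal phalanx.
All lengths are millimetres; the package works in a consistent mm-N-MPa
unit system throughout.

The box is voxelised onto a regular hexahedral grid (:class:`DesignDomain`)
that carries a per-voxel material density in [0, 1]; this grid is both the
finite-element mesh and the design space of the topology optimiser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "RecessSpec",
    "PadGeometryParams",
    "DesignDomain",
    "hole_centres",
    "build_design_domain",
    "solid_box",
]


class GeometryError(ValueError):
    """Raised when pad geometry parameters are inconsistent."""


@dataclass(frozen=True)
class RecessSpec:
    """Dorsoproximal recess modelling the proximal epiphysis.

    shape: "quarter_cylinder" (axis lateral, centred on the dorsoproximal
    edge) or "none". radius_mm defaults to 0.3 x pad height when left None.
    """

    shape: str = "quarter_cylinder"
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("quarter_cylinder", "none"):
            raise GeometryError(f"unknown recess shape {self.shape!r}")
        if self.radius_mm is not None and self.radius_mm <= 0:
            raise GeometryError("recess radius must be positive")

    def radius_for(self, height_mm: float) -> float:
        if self.shape == "none":
            return 0.0
        return self.radius_mm if self.radius_mm is not None else 0.3 * height_mm


@dataclass(frozen=True)
class PadGeometryParams:
    """Printed dimensions of the idealised pad model.

    Defaults are the published pad-model values: a 1.5 x 1.0 x 0.45 mm box
    with three longitudinal rows of five vertical holes (diameter 0.1 mm,
    0.14 mm centre-to-centre pitch within a row, 0.25 mm between rows).
    ``hole_field_offset_mm`` shifts the hole field longitudinally relative
    to the pad centre (0 centres it, matching the published rendering).
    """

    length_mm: float = 1.5
    width_mm: float = 1.0
    height_mm: float = 0.45
    hole_diameter_mm: float = 0.1
    hole_pitch_mm: float = 0.14
    row_spacing_mm: float = 0.25
    n_rows: int = 3
    holes_per_row: int = 5
    hole_field_offset_mm: float = 0.0
    recess: RecessSpec = field(default_factory=RecessSpec)

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "height_mm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.n_rows < 0 or self.holes_per_row < 0:
            raise GeometryError("hole counts must be non-negative")
        if self.n_holes:
            for name in ("hole_diameter_mm", "hole_pitch_mm", "row_spacing_mm"):
                if getattr(self, name) <= 0:
                    raise GeometryError(f"{name} must be strictly positive")
            if self.hole_pitch_mm < self.hole_diameter_mm and self.holes_per_row > 1:
                raise GeometryError(
                    "holes within a row overlap: pitch "
                    f"{self.hole_pitch_mm} mm < diameter {self.hole_diameter_mm} mm"
                )
            r = 0.5 * self.hole_diameter_mm
            row_span = (self.n_rows - 1) * self.row_spacing_mm
            if row_span + 2 * r > self.width_mm:
                raise GeometryError("hole rows exceed the pad width")
            x_span = (self.holes_per_row - 1) * self.hole_pitch_mm
            x_mid = 0.5 * self.length_mm + self.hole_field_offset_mm
            if x_mid - 0.5 * x_span - r < 0 or x_mid + 0.5 * x_span + r > self.length_mm:
                raise GeometryError("hole field exceeds the pad length")

    @property
    def n_holes(self) -> int:
        return self.n_rows * self.holes_per_row

    @property
    def mid_sagittal_y(self) -> float:
        return 0.5 * self.width_mm

    def hole_field_span_x(self) -> tuple[float, float]:
        """Longitudinal interval covered by the hole field (hole edges)."""
        r = 0.5 * self.hole_diameter_mm
        x_span = (self.holes_per_row - 1) * self.hole_pitch_mm
        x_mid = 0.5 * self.length_mm + self.hole_field_offset_mm
        return (x_mid - 0.5 * x_span - r, x_mid + 0.5 * x_span + r)

    def row_ordinates(self) -> np.ndarray:
        """Lateral (y) centrelines of the hole rows, symmetric about mid-sagittal."""
        j = np.arange(self.n_rows) - 0.5 * (self.n_rows - 1)
        return self.mid_sagittal_y + j * self.row_spacing_mm


def hole_centres(params: PadGeometryParams) -> np.ndarray:
    """Return the ``(n_rows * holes_per_row, 2)`` array of hole centres (x, y) in mm.

    Rows are symmetric about the mid-sagittal plane; within-row neighbours are
    separated by the centre-to-centre pitch.  Validation (overlap, footprint)
    happens at parameter construction.
    """
    if params.n_holes == 0:
        return np.empty((0, 2))
    ys = params.row_ordinates()
    i = np.arange(params.holes_per_row) - 0.5 * (params.holes_per_row - 1)
    xs = 0.5 * params.length_mm + params.hole_field_offset_mm + i * params.hole_pitch_mm
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class DesignDomain:
    """Voxel grid with per-voxel densities, masks, and face selectors.

    Arrays are indexed ``[ix, iy, iz]``.  ``void_mask`` marks permanently
    empty voxels (holes, recess); ``frozen_mask`` marks material that the
    optimiser may never remove.  ``symmetric`` turns on mirror symmetry
    about the mid-sagittal plane (y = width/2) for optimisation updates.
    """

    params: PadGeometryParams
    resolution: tuple[int, int, int]
    density: np.ndarray
    void_mask: np.ndarray
    frozen_mask: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        nx, ny, nz = self.resolution
        for arr, name in ((self.density, "density"), (self.void_mask, "void_mask"),
                          (self.frozen_mask, "frozen_mask")):
            if arr.shape != (nx, ny, nz):
                raise GeometryError(f"{name} shape {arr.shape} != resolution {self.resolution}")
        if np.any(self.density < -1e-12) or np.any(self.density > 1 + 1e-12):
            raise GeometryError("density must lie in [0, 1]")
        if np.any(self.density[self.void_mask] != 0):
            raise GeometryError("void voxels must have zero density")

    # -- grid metrics -----------------------------------------------------
    @property
    def voxel_size(self) -> tuple[float, float, float]:
        nx, ny, nz = self.resolution
        p = self.params
        return (p.length_mm / nx, p.width_mm / ny, p.height_mm / nz)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.resolution))

    @property
    def solid_mask(self) -> np.ndarray:
        return ~self.void_mask

    @property
    def design_mask(self) -> np.ndarray:
        """Voxels the optimiser may modify (solid and not frozen)."""
        return self.solid_mask & ~self.frozen_mask

    def centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D voxel-centre coordinate arrays per axis (mm)."""
        hx, hy, hz = self.voxel_size
        nx, ny, nz = self.resolution
        return (
            (np.arange(nx) + 0.5) * hx,
            (np.arange(ny) + 0.5) * hy,
            (np.arange(nz) + 0.5) * hz,
        )

    def volume_fraction(self) -> float:
        """Mean density over the initially solid voxels."""
        solid = self.solid_mask
        return float(self.density[solid].mean()) if solid.any() else 0.0

    def void_fraction(self) -> float:
        return float(self.void_mask.mean())

    # -- symmetry ---------------------------------------------------------
    def mirrored(self, arr: np.ndarray) -> np.ndarray:
        """Mirror a voxel array about the mid-sagittal plane."""
        return arr[:, ::-1, :]

    def symmetrise(self) -> None:
        """Project the density field onto exact mirror symmetry."""
        self.density = 0.5 * (self.density + self.mirrored(self.density))
        self.density[self.void_mask] = 0.0

    # -- face selectors ---------------------------------------------------
    FACES = ("ventral", "dorsal", "proximal", "distal", "lateral_left", "lateral_right")

    def face_voxels(self, face: str) -> np.ndarray:
        """Boolean voxel mask of the layer adjacent to a named face."""
        m = np.zeros(self.resolution, dtype=bool)
        if face == "ventral":
            m[:, :, 0] = True
        elif face == "dorsal":
            m[:, :, -1] = True
        elif face == "proximal":
            m[0, :, :] = True
        elif face == "distal":
            m[-1, :, :] = True
        elif face == "lateral_left":
            m[:, 0, :] = True
        elif face == "lateral_right":
            m[:, -1, :] = True
        else:
            raise GeometryError(f"unknown face {face!r}; one of {self.FACES}")
        return m

    def freeze_face_layer(self, face: str = "ventral") -> None:
        """Freeze the solid voxel layer at a face (protect it from removal)."""
        self.frozen_mask |= self.face_voxels(face) & self.solid_mask

    def copy(self) -> "DesignDomain":
        return DesignDomain(
            params=self.params,
            resolution=self.resolution,
            density=self.density.copy(),
            void_mask=self.void_mask.copy(),
            frozen_mask=self.frozen_mask.copy(),
            symmetric=self.symmetric,
        )


def build_design_domain(
    params: PadGeometryParams,
    resolution: tuple[int, int, int],
    *,
    with_recess: bool = True,
    strict: bool = True,
) -> DesignDomain:
    """Voxelise the pad model onto a regular grid.

    A voxel is void iff its centre lies inside a hole cylinder (full height)
    or inside the recess; density starts at 1 on solid voxels.  Resolutions
    that put fewer than two voxels across a hole diameter cannot resolve the
    ducts: this raises in strict mode and warns otherwise.
    """
    nx, ny, nz = resolution
    if nx < 10 or ny < 10 or nz < 5:
        raise GeometryError(f"resolution {resolution} below the minimum (10, 10, 5)")
    domain_params = params if with_recess else replace(params, recess=RecessSpec(shape="none"))

    hx, hy, hz = (params.length_mm / nx, params.width_mm / ny, params.height_mm / nz)
    if params.n_holes and params.hole_diameter_mm / max(hx, hy) < 2.0:
        msg = (
            f"resolution {resolution} puts fewer than 2 voxels across the "
            f"{params.hole_diameter_mm} mm hole diameter"
        )
        if strict:
            raise GeometryError(msg)
        warnings.warn(msg, stacklevel=2)

    cx, cy, cz = (
        (np.arange(nx) + 0.5) * hx,
        (np.arange(ny) + 0.5) * hy,
        (np.arange(nz) + 0.5) * hz,
    )
    void = np.zeros(resolution, dtype=bool)

    if params.n_holes:
        r2 = (0.5 * params.hole_diameter_mm) ** 2
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        in_hole = np.zeros((nx, ny), dtype=bool)
        for hcx, hcy in hole_centres(params):
            in_hole |= (xx - hcx) ** 2 + (yy - hcy) ** 2 < r2
        void |= in_hole[:, :, None]

    rr = domain_params.recess.radius_for(params.height_mm)
    if rr > 0:
        xx, zz = np.meshgrid(cx, cz, indexing="ij")
        in_recess = xx**2 + (zz - params.height_mm) ** 2 < rr**2
        void |= in_recess[:, None, :]

    density = np.where(void, 0.0, 1.0)
    return DesignDomain(
        params=domain_params,
        resolution=resolution,
        density=density,
        void_mask=void,
        frozen_mask=np.zeros(resolution, dtype=bool),
    )


def solid_box(
    length_mm: float,
    width_mm: float,
    height_mm: float,
    resolution: tuple[int, int, int],
) -> DesignDomain:
    """A fully solid box domain with no holes or recess (toy problems, tests)."""
    params = PadGeometryParams(
        length_mm=length_mm,
        width_mm=width_mm,
        height_mm=height_mm,
        n_rows=0,
        holes_per_row=0,
        recess=RecessSpec(shape="none"),
    )
    nx, ny, nz = resolution
    return DesignDomain(
        params=params,
        resolution=resolution,
        density=np.ones(resolution),
        void_mask=np.zeros(resolution, dtype=bool),
        frozen_mask=np.zeros(resolution, dtype=bool),
    )
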