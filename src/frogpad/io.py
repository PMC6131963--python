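"""Readers and writers: TOML config, legacy-VTK fields, CSV tables, STL surfaces.

VTK output uses the legacy ASCII STRUCTURED_POINTS format (voxel cell data
plus nodal point data), loadable by ParaView and friends.  The reader
implemented here is intentionally minimal: it reads back the files this
module writes (round-trip checks), not arbitrary VTK.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DesignDomain

__all__ = [
    "load_toml",
    "write_vtk",
    "read_vtk_cell_array",
    "write_stl",
    "write_trajectories_csv",
]


def load_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _flatten_cells(arr: np.ndarray) -> np.ndarray:
    """Voxel array [ix, iy, iz(, comp)] -> VTK ordering (x fastest)."""
    if arr.ndim == 3:
        return arr.transpose(2, 1, 0).reshape(-1)
    return arr.transpose(2, 1, 0, 3).reshape(-1, arr.shape[-1])


def write_vtk(
    path: str | Path,
    domain: DesignDomain,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write a legacy ASCII VTK structured-points file of the voxel grid.

    ``cell_data`` arrays are (nx, ny, nz) scalars or (nx, ny, nz, 3)
    vectors; ``point_data`` arrays are (n_nodes,) or (n_nodes, 3) in the
    package's node ordering.
    """
    path = Path(path)
    nx, ny, nz = domain.resolution
    hx, hy, hz = domain.voxel_size
    lines = [
        "# vtk DataFile Version 3.0",
        "frogpad voxel fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {hx:.9g} {hy:.9g} {hz:.9g}",
    ]

    def emit(name: str, arr: np.ndarray, vec: bool) -> None:
        if vec:
            lines.append(f"VECTORS {name} double")
            for row in arr:
                lines.append(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}")
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.12g}" for v in arr)

    if cell_data:
        lines.append(f"CELL_DATA {nx * ny * nz}")
        for name, arr in cell_data.items():
            flat = _flatten_cells(np.asarray(arr, dtype=float))
            emit(name, flat, vec=flat.ndim == 2)
    if point_data:
        lines.append(f"POINT_DATA {(nx + 1) * (ny + 1) * (nz + 1)}")
        for name, arr in point_data.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim == 2:
                a4 = a.reshape(nx + 1, ny + 1, nz + 1, 3)
                flat = a4.transpose(2, 1, 0, 3).reshape(-1, 3)
            else:
                flat = a.reshape(nx + 1, ny + 1, nz + 1).transpose(2, 1, 0).reshape(-1)
            emit(name, flat, vec=flat.ndim == 2)

    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_cell_array(path: str | Path, name: str) -> np.ndarray:
    """Read back a scalar cell array written by :func:`write_vtk` as [ix, iy, iz]."""
    lines = Path(path).read_text().splitlines()
    dims = next(l for l in lines if l.startswith("DIMENSIONS")).split()[1:]
    nx, ny, nz = (int(d) - 1 for d in dims)
    i = lines.index(f"SCALARS {name} double 1")
    vals = np.array([float(v) for v in lines[i + 2 : i + 2 + nx * ny * nz]])
    return vals.reshape(nz, ny, nx).transpose(2, 1, 0)


def write_stl(path: str | Path, domain: DesignDomain, threshold: float = 0.5) -> Path:
    """Export the thresholded density field as an STL surface mesh.

    Marching cubes on the zero-padded density volume (so the boundary of the
    box is closed) at the given iso-level.
    """
    import trimesh
    from skimage import measure

    path = Path(path)
    vol = np.pad(np.where(domain.void_mask, 0.0, domain.density), 1)
    verts, faces, _, _ = measure.marching_cubes(vol, level=threshold)
    h = np.array(domain.voxel_size)
    # voxel index space -> mm: cell centres sit at (i + 0.5) h; padding shifts by one
    verts_mm = (verts - 0.5) * h
    mesh = trimesh.Trimesh(vertices=verts_mm, faces=faces, process=True)
    mesh.export(str(path))
    return path


def write_trajectories_csv(path: str | Path, trajectories) -> Path:
    """CSV with columns trajectory_id,x,y,z (one row per integration point)."""
    rows = []
    for tid, t in enumerate(trajectories):
        for pt in t.points:
            rows.append((tid, pt[0], pt[1], pt[2]))
    df = pd.DataFrame(rows, columns=["trajectory_id", "x", "y", "z"])
    df.to_csv(path, index=False)
    return Path(path)
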