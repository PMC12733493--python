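"""Volumetric file I/O: OpenDX and Gaussian CUBE.

Converged distribution functions are exported for isosurface viewers
(VMD, PyMOL, ChimeraX).  OpenDX files go through the gridData package and
are written in Angstrom; CUBE files follow the Gaussian convention (Bohr,
atom records in the header) and carry the solute so viewers superimpose
the density on the structure.
"""

from __future__ import annotations

import numpy as np
from gridData import Grid

from .errors import RismHydraError
from .grid import GridSpec
from .units import BOHR

__all__ = ["write_dx", "read_dx", "write_cube", "read_cube",
           "write_volumetric"]

_ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "BR": 35,
    "SE": 34, "I": 53, "AR": 18,
}


def _check_field(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.shape != tuple(grid.shape):
        raise RismHydraError(
            f"field shape {field.shape} does not match grid {grid.shape}")
    bad = np.argwhere(~np.isfinite(field))
    if len(bad):
        i, j, k = bad[0]
        raise RismHydraError(
            f"field contains non-finite values (first at voxel "
            f"[{i}, {j}, {k}]); refusing to write")
    return field


def write_dx(field: np.ndarray, grid: GridSpec, path) -> None:
    """Write an OpenDX scalar field (Angstrom units)."""
    field = _check_field(field, grid)
    g = Grid(field, origin=np.array(grid.origin),
             delta=np.array(grid.spacing))
    g.export(str(path), file_format="dx")


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    g = Grid(str(path))
    delta = np.diag(g.delta) if np.ndim(g.delta) == 2 else np.asarray(g.delta)
    spec = GridSpec(origin=tuple(float(x) for x in g.origin),
                    spacing=tuple(float(x) for x in delta),
                    shape=tuple(int(n) for n in g.grid.shape))
    return np.asarray(g.grid, dtype=float), spec


def write_cube(field: np.ndarray, grid: GridSpec, path,
               solute=None, comment: str = "rismhydra field") -> None:
    """Write a Gaussian CUBE file (header in Bohr, per the format spec)."""
    field = _check_field(field, grid)
    origin = np.array(grid.origin) / BOHR
    spacing = np.array(grid.spacing) / BOHR
    atoms = solute.atoms if solute is not None else []
    with open(path, "w") as fh:
        fh.write(comment + "\n")
        fh.write("scalar field written by rismhydra (distribution function)\n")
        fh.write(f"{len(atoms):5d}{origin[0]:12.6f}{origin[1]:12.6f}"
                 f"{origin[2]:12.6f}\n")
        for axis in range(3):
            step = [0.0, 0.0, 0.0]
            step[axis] = spacing[axis]
            fh.write(f"{grid.shape[axis]:5d}{step[0]:12.6f}{step[1]:12.6f}"
                     f"{step[2]:12.6f}\n")
        for a in atoms:
            z = _ELEMENT_Z.get(a.element.upper(), 0)
            p = np.array(a.position) / BOHR
            fh.write(f"{z:5d}{float(a.charge):12.6f}{p[0]:12.6f}"
                     f"{p[1]:12.6f}{p[2]:12.6f}\n")
        flat = field.ravel()  # x outer, z inner: C order of (nx, ny, nz)
        for start in range(0, len(flat), 6):
            chunk = flat[start:start + 6]
            fh.write("".join(f"{v:16.8e}" for v in chunk) + "\n")


def read_cube(path) -> tuple[np.ndarray, GridSpec, list]:
    """Read a Gaussian CUBE file back to (field, grid, atom records)."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        rec = fh.readline().split()
        n_atoms = int(rec[0])
        origin = np.array([float(v) for v in rec[1:4]]) * BOHR
        shape = []
        spacing = []
        for axis in range(3):
            rec = fh.readline().split()
            shape.append(int(rec[0]))
            step = [float(v) for v in rec[1:4]]
            spacing.append(step[axis] * BOHR)
        atoms = []
        for _ in range(abs(n_atoms)):
            rec = fh.readline().split()
            atoms.append((int(rec[0]), float(rec[1]),
                          tuple(float(v) * BOHR for v in rec[2:5])))
        data = np.array(fh.read().split(), dtype=float)
    field = data.reshape(shape)
    spec = GridSpec(origin=tuple(origin), spacing=tuple(spacing),
                    shape=tuple(shape))
    return field, spec, atoms


def write_volumetric(field: np.ndarray, grid: GridSpec, path,
                     file_format: str = "dx", solute=None) -> None:
    """Dispatch to the DX or CUBE writer."""
    if file_format == "dx":
        write_dx(field, grid, path)
    elif file_format == "cube":
        write_cube(field, grid, path, solute=solute)
    else:
        raise ValueError(f"format must be 'dx' or 'cube', got {file_format!r}")
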