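"""Cartesian solvation grids and FFT bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridSizeError, InvalidModelError

__all__ = ["GridSpec", "build_grid", "fft_friendly"]

#: Default memory ceiling for one solvation grid stack (bytes).  The solver
#: holds roughly a dozen double fields per solvent site.
DEFAULT_MEMORY_CEILING = 4 * 1024 ** 3
_FIELDS_PER_SITE = 12


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned Cartesian box: origin (A), spacing per axis (A), shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise InvalidModelError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise InvalidModelError("grid needs at least 2 points per axis")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def lengths(self) -> np.ndarray:
        return np.array(self.shape) * np.array(self.spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3))

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array (x fastest-varying last axis)."""
        ax = self.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def k_lattice(self):
        """Angular wavevector components on the rfftn lattice.

        Returns (kx, ky, kz) broadcastable to the rfftn output shape and
        the magnitude |k|.
        """
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        kx = 2 * np.pi * np.fft.fftfreq(nx, dx)[:, None, None]
        ky = 2 * np.pi * np.fft.fftfreq(ny, dy)[None, :, None]
        kz = 2 * np.pi * np.fft.rfftfreq(nz, dz)[None, None, :]
        kmag = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
        return (kx, ky, kz), kmag

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        lo = np.array(self.origin) - margin
        hi = np.array(self.origin) + (np.array(self.shape) - 1) * np.array(
            self.spacing) + margin
        return np.all((points >= lo) & (points <= hi), axis=1)


def fft_friendly(n: int) -> int:
    """Smallest even integer >= n whose prime factors are all in {2,3,5,7}."""
    def smooth(m: int) -> bool:
        for p in (2, 3, 5, 7):
            while m % p == 0:
                m //= p
        return m == 1

    m = max(int(n), 2)
    if m % 2:
        m += 1
    while not smooth(m):
        m += 2
    return m


def build_grid(solute, buffer: float = 12.0, spacing: float = 0.25,
               memory_ceiling: int = DEFAULT_MEMORY_CEILING,
               n_sites: int = 2) -> GridSpec:
    """Box covering the solute plus ``buffer`` (A) on all sides.

    Shapes are rounded up to even 7-smooth sizes for FFT efficiency; the
    box is grown symmetrically so the solute stays centred.  An explicit
    :class:`GridSizeError` (with the required byte count) is raised when
    the expected solver working set exceeds ``memory_ceiling``.
    """
    if buffer <= 0:
        raise InvalidModelError("buffer must be positive")
    if spacing <= 0:
        raise InvalidModelError("spacing must be positive")
    lo, hi = solute.extents()
    centre = 0.5 * (lo + hi)
    span = (hi - lo) + 2.0 * buffer
    shape = tuple(fft_friendly(int(np.ceil(s / spacing)) + 1) for s in span)
    required = int(np.prod(shape)) * 8 * _FIELDS_PER_SITE * n_sites
    if required > memory_ceiling:
        raise GridSizeError(
            f"grid {shape} needs ~{required / 1024**3:.1f} GiB "
            f"(> ceiling {memory_ceiling / 1024**3:.1f} GiB); "
            "increase spacing or raise the ceiling",
            required_bytes=required)
    origin = tuple(centre[i] - 0.5 * (shape[i] - 1) * spacing
                   for i in range(3))
    return GridSpec(origin=origin, spacing=(spacing,) * 3, shape=shape)
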