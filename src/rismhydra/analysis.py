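"""Hydration-shell analysis of converged 3D solvent distributions.

Given g_Ow(r) (and g_Hw(r)) around a solute, this module derives the
quantities a hydration study reports:

* the cumulative water count n(r_cut) versus distance to the solute and
  its derivative, the shell-resolved relative solvent density;
* the hydration-shell boundary r_cut* — the first minimum of the shell
  density after its first peak (a shell shows enhanced density inside and
  depleted density at its boundary, so the minimum marks the edge);
* the total hydration number (the density-weighted integral of g_Ow over
  the shell), per-pocket water counts via nearest-residue partitioning,
  an H-bonded water fraction from geometric sphere integrals of g_Hw/g_Ow
  around polar atoms, and the Shrake-Rupley solvent-accessible surface
  area.

"Distance to the solute" defaults to nearest-atom-centre distance; a
van-der-Waals-surface variant (subtracting each atom's radius) is
selectable and recorded in the profile provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidModelError, NoBoundaryError, RismHydraError
from .grid import GridSpec
from .solute import SoluteSystem

__all__ = [
    "DistanceField", "ShellProfile", "PocketSpec", "HydrationReport",
    "distance_transform", "shell_profile", "find_shell_boundary",
    "hydration_number", "hbond_fraction", "pocket_hydration",
    "nearest_residue_labels", "sasa", "sphere_points",
    "SUDLOW_SITE_I", "SUDLOW_SITE_II", "analyze_fields",
]

#: Residue lists of serum albumin's two high-affinity drug-binding pockets
#: (Sudlow sites I and II, subdomains IIA and IIIA).
SUDLOW_SITE_I = (
    ("TYR", 150), ("LYS", 195), ("GLN", 196), ("ARG", 197), ("LEU", 198),
    ("LYS", 199), ("CYS", 200), ("ALA", 201), ("SER", 202), ("LEU", 203),
    ("GLN", 204), ("PHE", 211), ("TRP", 214), ("ALA", 215), ("ARG", 218),
    ("LEU", 219), ("ARG", 222), ("PHE", 223), ("LEU", 234), ("LEU", 238),
    ("VAL", 241), ("HIS", 242), ("CYS", 245), ("CYS", 246), ("HIS", 247),
    ("CYS", 253), ("ARG", 257), ("LEU", 260), ("ALA", 261), ("ILE", 264),
    ("ILE", 290), ("ALA", 291), ("GLU", 292),
)
SUDLOW_SITE_II = (
    ("PRO", 384), ("LEU", 387), ("ILE", 388), ("ASN", 391), ("CYS", 392),
    ("PHE", 395), ("ARG", 410), ("TYR", 411), ("LYS", 414), ("LEU", 430),
    ("VAL", 433), ("CYS", 438), ("ALA", 449), ("GLU", 450), ("LEU", 453),
    ("VAL", 455), ("ARG", 485), ("SER", 489),
)


@dataclass
class DistanceField:
    """Per-voxel distance to the solute (A) plus nearest-atom indices."""

    values: np.ndarray
    grid: GridSpec
    nearest_atom: np.ndarray
    definition: str = "atom-centre"

    @property
    def max_distance(self) -> float:
        return float(self.values.max())


@dataclass
class ShellProfile:
    """Cumulative water count and shell-resolved density vs r_cut.

    ``edges`` are bin edges (A); ``n`` is n(r_cut) evaluated at the edges;
    ``n_prime`` (count/A) and ``shell_density`` (relative to bulk) live at
    the bin ``centers``.  ``shell_density`` is n' divided by the measured
    shell volume per unit thickness, so box-shape artefacts cancel and the
    profile tends to 1 in bulk.
    """

    edges: np.ndarray
    n: np.ndarray
    n_prime: np.ndarray
    shell_density: np.ndarray
    rho: float
    provenance: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass(frozen=True)
class PocketSpec:
    """A named set of residues delimiting a binding-pocket region."""

    name: str
    residues: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.residues:
            raise InvalidModelError(f"pocket {self.name!r} has no residues")


@dataclass
class HydrationReport:
    shell_thickness: float            # A
    n_total: float
    hbond_fraction: float
    pocket_counts: dict[str, float]
    sasa_total: float                 # A^2
    weak_shell: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.hbond_fraction <= 1.0):
            raise InvalidModelError("hbond_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# distance transform
# ---------------------------------------------------------------------------

def distance_transform(solute: SoluteSystem, grid: GridSpec,
                       definition: str = "atom-centre") -> DistanceField:
    """Exact nearest-atom distance at every grid point (KD-tree).

    ``definition='vdw-surface'`` subtracts each atom's van der Waals radius
    (clamped at zero); the variant used is recorded on the field.
    """
    if definition not in ("atom-centre", "vdw-surface"):
        raise ValueError("definition must be 'atom-centre' or 'vdw-surface'")
    pts = grid.points()
    tree = cKDTree(solute.positions)
    if definition == "atom-centre":
        d, idx = tree.query(pts)
    else:
        # nearest vdW surface needs all candidate atoms; query enough
        # neighbours that the radius correction cannot change the winner.
        k = min(len(solute), 8)
        dists, idxs = tree.query(pts, k=k)
        dists = np.atleast_2d(dists.T).T
        idxs = np.atleast_2d(idxs.T).T
        radii = solute.vdw_radii
        surf = dists - radii[idxs]
        win = np.argmin(surf, axis=1)
        rows = np.arange(len(pts))
        d = np.maximum(surf[rows, win], 0.0)
        idx = idxs[rows, win]
    return DistanceField(values=d.reshape(grid.shape), grid=grid,
                         nearest_atom=idx.reshape(grid.shape),
                         definition=definition)


# ---------------------------------------------------------------------------
# shell profile and boundary
# ---------------------------------------------------------------------------

def shell_profile(g_ow: np.ndarray, dist: DistanceField, rho: float,
                  bin_width: float | None = None, r_max: float | None = None,
                  smooth: bool = False) -> ShellProfile:
    """Bin the density-weighted water count by distance to the solute.

    n(r_cut) = rho * sum_{d <= r_cut} g_Ow dV, accumulated on bins of
    ``bin_width`` (default: the grid spacing); n' is the per-bin increment
    divided by the bin width (the central difference of n at bin centres);
    the shell density divides n' by rho times the measured volume per unit
    thickness of the same bin, i.e. it is the mean g over the shell.
    Optional 5-point smoothing steadies the profile for boundary detection.
    """
    grid = dist.grid
    spacing = max(grid.spacing)
    if bin_width is None:
        bin_width = spacing
    if bin_width < spacing - 1e-12:
        raise InvalidModelError(
            f"bin width {bin_width} below grid spacing {spacing}: "
            "the derivative would alias")
    if g_ow.shape != dist.values.shape:
        raise InvalidModelError("field and distance grid shapes differ")
    if r_max is None:
        # stay clear of the box corners where shells are truncated
        r_max = float(dist.max_distance)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    d = dist.values.ravel()
    gv = g_ow.ravel()
    dV = grid.voxel_volume
    mass, _ = np.histogram(d, bins=edges, weights=gv)
    counts, _ = np.histogram(d, bins=edges)
    n = np.concatenate([[0.0], np.cumsum(mass)]) * rho * dV
    n_prime = rho * dV * mass / bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        shell_density = np.where(counts > 0, mass / np.maximum(counts, 1), np.nan)
    if smooth:
        kernel = np.ones(5) / 5.0
        pad = np.pad(shell_density, 2, mode="edge")
        shell_density = np.convolve(pad, kernel, mode="valid")
    return ShellProfile(edges=edges, n=n, n_prime=n_prime,
                        shell_density=shell_density, rho=rho,
                        provenance={"bin_width": bin_width,
                                    "distance_definition": dist.definition,
                                    "smoothed": smooth})


def find_shell_boundary(profile: ShellProfile) -> tuple[float, bool]:
    """First local minimum of the shell density after its first peak.

    Returns ``(r_cut_star, weak)`` where ``weak`` flags a minimum whose
    shell density is not depleted below bulk (>= 1).  The minimum position
    is refined by a parabolic fit through the bracketing bins.  A profile
    with no first peak above bulk, or no subsequent minimum, raises
    :class:`NoBoundaryError` — the solvent is bulk-like.
    """
    rho_rel = profile.shell_density
    centers = profile.centers
    valid = np.isfinite(rho_rel)
    if valid.sum() < 3:
        raise NoBoundaryError("profile has fewer than 3 usable bins")
    y = rho_rel[valid]
    x = centers[valid]

    peak = None
    for i in range(1, len(y) - 1):
        if y[i] > 1.0 and y[i] >= y[i - 1] and y[i] > y[i + 1]:
            peak = i
            break
    if peak is None:
        raise NoBoundaryError(
            "no shell: the density profile never peaks above bulk")
    trough = None
    for i in range(peak + 1, len(y) - 1):
        if y[i] <= y[i - 1] and y[i] < y[i + 1]:
            trough = i
            break
    if trough is None:
        raise NoBoundaryError(
            "no boundary: the density profile has no minimum after "
            "its first peak")
    # parabolic refinement through the three bracketing bins
    x0, x1, x2 = x[trough - 1:trough + 2]
    y0, y1, y2 = y[trough - 1:trough + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if abs(denom) > 1e-15:
        offset = 0.5 * (y0 - y2) / denom
        offset = float(np.clip(offset, -1.0, 1.0))
    else:
        offset = 0.0
    r_star = float(x1 + offset * profile.bin_width)
    weak = bool(y[trough] >= 1.0)
    if weak:
        warnings.warn("shell-density minimum is not depleted below bulk "
                      "(weak shell)", stacklevel=2)
    return r_star, weak


# ---------------------------------------------------------------------------
# hydration numbers
# ---------------------------------------------------------------------------

def hydration_number(g_ow: np.ndarray, dist: DistanceField, r_cut: float,
                     rho: float) -> float:
    """n_tot = rho * sum over voxels with d <= r_cut of g_Ow dV."""
    if r_cut > dist.max_distance:
        raise RismHydraError(
            f"r_cut {r_cut:.2f} A exceeds the distance-field range "
            f"({dist.max_distance:.2f} A)")
    mask = dist.values <= r_cut
    return float(rho * dist.grid.voxel_volume * g_ow[mask].sum())


def nearest_residue_labels(solute: SoluteSystem, dist: DistanceField) -> np.ndarray:
    """Per-voxel index of the residue owning the nearest solute atom."""
    return solute.residue_index()[dist.nearest_atom]


def pocket_hydration(g_ow: np.ndarray, dist: DistanceField,
                     solute: SoluteSystem, pocket: PocketSpec,
                     r_cut: float, rho: float) -> float:
    """Water count of the first-shell voxels nearest to pocket residues.

    The first shell is partitioned by Voronoi-style nearest-residue
    assignment, so counts over a full residue partition sum exactly to the
    total hydration number.
    """
    residues = solute.residues
    wanted = set(pocket.residues)
    keep = np.array([(name, num) in wanted for _, num, name in residues])
    present = {(name, num) for _, num, name in residues}
    missing = [r for r in pocket.residues if r not in present]
    if missing:
        raise RismHydraError(
            f"pocket {pocket.name!r} names residues absent from the solute: "
            f"{missing}")
    labels = nearest_residue_labels(solute, dist)
    mask = (dist.values <= r_cut) & keep[labels]
    return float(rho * dist.grid.voxel_volume * g_ow[mask].sum())


# ---------------------------------------------------------------------------
# hydrogen-bonded fraction
# ---------------------------------------------------------------------------

def _polar_classification(solute: SoluteSystem, bond_cut: float = 1.25):
    """Split solute N/O atoms into acceptors and H-bond-donor heavies.

    An N or O atom is always counted as an acceptor; it additionally
    donates when a hydrogen sits within ``bond_cut`` A (a covalent N-H/O-H
    bond).
    """
    pos = solute.positions
    elements = [a.element.upper() for a in solute.atoms]
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    polar_idx = [i for i, e in enumerate(elements) if e in ("N", "O")]
    donors = []
    if h_idx and polar_idx:
        htree = cKDTree(pos[h_idx])
        for i in polar_idx:
            if htree.query_ball_point(pos[i], bond_cut):
                donors.append(i)
    return polar_idx, donors


def hbond_fraction(g_hw: np.ndarray, g_ow: np.ndarray,
                   solute: SoluteSystem, dist: DistanceField,
                   r_cut: float, n_total: float, rho: float, *,
                   r_acceptor: float = 2.6, r_donor: float = 3.5
                   ) -> float:
    """Fraction of first-shell waters H-bonded to the solute.

    Counts hydrogen density within ``r_acceptor`` (A) of solute N/O
    acceptors (solvent donates to solute) plus oxygen density within
    ``r_donor`` of solute donor heavy atoms (solute donates to solvent),
    both restricted to the first shell; the count is divided by ``n_total``
    and clamped to [0, 1] with a warning if clamping was needed.  The
    hydrogen site density is twice the molecular density (two equivalent
    hydrogens per water).
    """
    acceptors, donors = _polar_classification(solute)
    if not acceptors and not donors:
        warnings.warn("solute has no polar atoms; H-bond fraction is 0",
                      stacklevel=2)
        return 0.0
    grid = dist.grid
    pts = grid.points()
    shell = (dist.values <= r_cut).ravel()
    dV = grid.voxel_volume
    count = 0.0
    if acceptors:
        atree = cKDTree(solute.positions[acceptors])
        near = atree.query_ball_point(pts[shell], r_acceptor)
        sel = np.zeros(shell.sum(), dtype=bool)
        sel[[i for i, lst in enumerate(near) if lst]] = True
        # hydrogen count / 2 -> water-molecule count
        count += 0.5 * (2.0 * rho) * dV * g_hw.ravel()[shell][sel].sum()
    if donors:
        dtree = cKDTree(solute.positions[donors])
        near = dtree.query_ball_point(pts[shell], r_donor)
        sel = np.zeros(shell.sum(), dtype=bool)
        sel[[i for i, lst in enumerate(near) if lst]] = True
        count += rho * dV * g_ow.ravel()[shell][sel].sum()
    if n_total <= 0:
        return 0.0
    fraction = count / n_total
    if fraction > 1.0:
        warnings.warn(f"H-bond count exceeded the shell population "
                      f"(fraction {fraction:.2f}); clamped to 1",
                      stacklevel=2)
        fraction = 1.0
    return float(fraction)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(solute: SoluteSystem, probe: float = 1.4, n_points: int = 960
         ) -> tuple[float, dict[tuple[str, int, str], float]]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is inflated by ``probe`` (A) and covered with ``n_points``
    golden-spiral quadrature points; a point is exposed iff it lies outside
    every other inflated sphere.  Returns the total area (A^2) and a
    per-residue breakdown.  Zero-radius atoms contribute the bare probe
    sphere.
    """
    pos = solute.positions
    radii = solute.vdw_radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(pos)
    reach = 2.0 * float(radii.max())
    residues = solute.residues
    res_idx = solute.residue_index()
    per_residue = {key: 0.0 for key in residues}
    total = 0.0
    for i in range(len(solute)):
        pts = pos[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(pos[i], reach)
                      if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - pos[j], axis=1)
            exposed &= d >= radii[j]
        area = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points
        total += area
        per_residue[residues[res_idx[i]]] += area
    return float(total), per_residue


# ---------------------------------------------------------------------------
# one-call report
# ---------------------------------------------------------------------------

def analyze_fields(fields, solute: SoluteSystem, rho: float, *,
                   pockets: tuple[PocketSpec, ...] = (),
                   bin_width: float | None = None,
                   r_cut: float | None = None,
                   probe: float = 1.4, sasa_points: int = 960,
                   smooth_profile: bool = False) -> HydrationReport:
    """Full hydration report from a converged :class:`SolvationFieldSet`."""
    dist = distance_transform(solute, fields.grid)
    profile = shell_profile(fields.g["Ow"], dist, rho, bin_width=bin_width,
                            smooth=smooth_profile)
    weak = False
    if r_cut is None:
        r_cut, weak = find_shell_boundary(profile)
    n_tot = hydration_number(fields.g["Ow"], dist, r_cut, rho)
    if "Hw" in fields.g:
        frac = hbond_fraction(fields.g["Hw"], fields.g["Ow"], solute, dist,
                              r_cut, n_tot, rho)
    else:
        frac = 0.0
    pocket_counts = {p.name: pocket_hydration(fields.g["Ow"], dist, solute,
                                              p, r_cut, rho)
                     for p in pockets}
    area, _ = sasa(solute, probe=probe, n_points=sasa_points)
    return HydrationReport(
        shell_thickness=float(r_cut), n_total=n_tot, hbond_fraction=frac,
        pocket_counts=pocket_counts, sasa_total=area, weak_shell=weak,
        provenance={"distance_definition": dist.definition,
                    "rho": rho, "probe": probe,
                    "sasa_points": sasa_points,
                    "solver": dict(getattr(fields, "provenance", {}))})
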