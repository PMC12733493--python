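"""Synthetic inputs for every pipeline stage — no downloads required.

Real protein runs need a prepared structure; everything else the solver
and analysis stages do can be exercised on constructed inputs whose ground
truth is known analytically:

* toy parameterized solutes (LJ spheres, ions, rigid few-atom molecules,
  random zero-net-charge polyatomics),
* radial density fields painted onto a grid through the same distance
  transform the analysis uses, so grid integrals have 1D quadrature
  oracles,
* synthetic shell-density profiles with a constructed first peak and
  trough (enhanced density inside the shell, depleted at its boundary)
  for boundary-finder recovery tests.

Every fixture is reproducible: the same recipe and seed give identical
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import DistanceField, ShellProfile, distance_transform
from .errors import FixtureError
from .grid import GridSpec
from .solute import SoluteAtom, SoluteSystem

__all__ = [
    "FixtureRecipe", "make_toy_solute", "paint_radial_field",
    "make_shell_profile", "two_gaussian_profile",
]

_KINDS = ("lj_sphere", "ion", "rigid_water_solute", "polyatomic_random")


@dataclass(frozen=True)
class FixtureRecipe:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS + ("painted_field", "shell_profile"):
            raise FixtureError(f"unknown fixture kind {self.kind!r}")


def make_toy_solute(recipe: FixtureRecipe) -> SoluteSystem:
    """Build a parameterized toy solute from a recipe.

    Kinds:

    ``lj_sphere``
        one neutral (or charged, via ``q``) LJ site; parameters ``sigma``,
        ``epsilon``, ``q``, ``radius``.
    ``ion``
        one charged site; parameters ``q`` (required), ``sigma``,
        ``epsilon``, ``radius``.
    ``rigid_water_solute``
        a rigid SPC/E-geometry water used as a 3-site solute.
    ``polyatomic_random``
        ``n`` atoms drawn uniformly in a sphere of ``radius_sphere`` with
        LJ parameters jittered around ``sigma``/``epsilon`` and charges
        shifted to zero net charge by construction.
    """
    p = dict(recipe.parameters)
    kind = recipe.kind

    def atom(serial, name, pos, q, sig, eps, rad, res="TOY", num=1):
        if sig < 0 or eps < 0 or rad < 0:
            raise FixtureError(
                f"recipe {kind!r}: negative LJ/radius parameter")
        return SoluteAtom(serial, name, name[:2].capitalize().rstrip("0123456789"),
                          res, num, "A", tuple(pos), q, sig, eps, rad)

    if kind == "lj_sphere":
        a = atom(1, "Ar", (0.0, 0.0, 0.0), p.get("q", 0.0),
                 p.get("sigma", 3.15), p.get("epsilon", 0.15),
                 p.get("radius", 1.77))
        return SoluteSystem([a], provenance={"fixture": "lj_sphere"})

    if kind == "ion":
        if "q" not in p:
            raise FixtureError("ion recipe requires a charge 'q'")
        a = atom(1, "Ion", (0.0, 0.0, 0.0), float(p["q"]),
                 p.get("sigma", 4.4), p.get("epsilon", 0.1),
                 p.get("radius", 2.2), res="ION")
        return SoluteSystem([a], provenance={"fixture": "ion"})

    if kind == "rigid_water_solute":
        half = np.deg2rad(109.47) / 2
        l = 1.0
        atoms = [
            atom(1, "O", (0.0, 0.0, 0.0), -0.8476, 3.166, 0.1553, 1.58,
                 res="HOH"),
            atom(2, "H1", (l * np.sin(half), 0.0, l * np.cos(half)),
                 0.4238, 1.1657, 0.01553, 1.2, res="HOH"),
            atom(3, "H2", (-l * np.sin(half), 0.0, l * np.cos(half)),
                 0.4238, 1.1657, 0.01553, 1.2, res="HOH"),
        ]
        return SoluteSystem(atoms, provenance={"fixture": "rigid_water_solute"})

    if kind == "polyatomic_random":
        n = int(p.get("n", 10))
        if n < 1:
            raise FixtureError("polyatomic_random needs n >= 1")
        rng = np.random.default_rng(recipe.seed)
        r_sph = float(p.get("radius_sphere", 4.0))
        # uniform in a ball
        u = rng.random(n) ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = r_sph * u[:, None] * v
        charges = rng.uniform(-0.5, 0.5, n)
        charges -= charges.mean()          # zero net charge by construction
        sig = p.get("sigma", 3.2) * rng.uniform(0.9, 1.1, n)
        eps = p.get("epsilon", 0.12) * rng.uniform(0.8, 1.2, n)
        atoms = [atom(i + 1, f"X{i + 1}", pos[i], float(charges[i]),
                      float(sig[i]), float(eps[i]), float(sig[i]) / 2.0,
                      res="RND", num=1 + i // 5)
                 for i in range(n)]
        return SoluteSystem(atoms, provenance={
            "fixture": "polyatomic_random", "seed": recipe.seed, "n": n})

    raise FixtureError(f"recipe kind {kind!r} does not build a solute")


def paint_radial_field(profile, solute: SoluteSystem, grid: GridSpec,
                       dist: DistanceField | None = None) -> np.ndarray:
    """Evaluate ``profile(d)`` at every voxel's distance to the solute.

    Uses the same distance transform as the analysis stage, so painted
    fields have exactly known radial structure.  ``profile`` must be
    finite over [0, max grid distance].
    """
    if dist is None:
        dist = distance_transform(solute, grid)
    values = np.asarray(profile(dist.values), dtype=float)
    if not np.all(np.isfinite(values)):
        raise FixtureError("profile produced non-finite values in range")
    return values


def two_gaussian_profile(peak_pos: float = 2.8, peak_amp: float = 1.5,
                         peak_width: float = 0.18, trough_pos: float = 4.0,
                         trough_amp: float = 0.4, trough_width: float = 0.32):
    """Bulk plus an enhancement Gaussian and a depletion Gaussian.

    g(d) = 1 + A_p exp(-(d-p)^2/w_p) - A_t exp(-(d-t)^2/w_t); widths enter
    unnormalized, as variance-like denominators.
    """
    def profile(d):
        d = np.asarray(d, dtype=float)
        return (1.0
                + peak_amp * np.exp(-(d - peak_pos) ** 2 / peak_width)
                - trough_amp * np.exp(-(d - trough_pos) ** 2 / trough_width))
    return profile


def make_shell_profile(seed: int = 0, *, n_bins: int = 120,
                       bin_width: float = 0.1, rho: float = 0.03332,
                       peak_pos_range: tuple[float, float] = (2.2, 3.4),
                       peak_amp_range: tuple[float, float] = (0.5, 2.5),
                       trough_offset_range: tuple[float, float] = (0.8, 1.8),
                       trough_amp_range: tuple[float, float] = (0.1, 0.6),
                       width_range: tuple[float, float] = (0.1, 0.4),
                       ) -> tuple[ShellProfile, dict]:
    """A randomized synthetic shell profile with known extrema.

    Draws peak/trough positions, amplitudes and widths, constructs the
    two-Gaussian shell density analytically on a 1D distance grid (a
    spherical-solute geometry, volume-per-thickness 4 pi r^2), and returns
    the :class:`ShellProfile` plus the analytic ground truth (exact
    numerically located peak/trough of the continuous profile).
    """
    if peak_amp_range[0] < 0 or trough_amp_range[0] < 0:
        raise FixtureError("amplitude ranges must be non-negative")
    rng = np.random.default_rng(seed)
    peak_pos = rng.uniform(*peak_pos_range)
    peak_amp = rng.uniform(*peak_amp_range)
    trough_pos = peak_pos + rng.uniform(*trough_offset_range)
    trough_amp = rng.uniform(*trough_amp_range)
    w_p = rng.uniform(*width_range)
    w_t = rng.uniform(*width_range)
    prof = two_gaussian_profile(peak_pos, peak_amp, w_p,
                                trough_pos, trough_amp, w_t)
    edges = bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_density = prof(centers)
    vol_per_thickness = 4.0 * np.pi * centers ** 2
    n_prime = rho * shell_density * vol_per_thickness
    n = np.concatenate([[0.0], np.cumsum(n_prime) * bin_width])
    # analytic extrema of the continuous profile, located on a fine grid
    fine = np.linspace(0.0, edges[-1], 200001)
    y = prof(fine)
    i_pk = int(np.argmax(y))
    i_tr = i_pk + int(np.argmin(y[i_pk:]))
    truth = {"peak_pos": float(fine[i_pk]), "trough_pos": float(fine[i_tr]),
             "peak_value": float(y[i_pk]), "trough_value": float(y[i_tr]),
             "parameters": {"peak_pos": peak_pos, "peak_amp": peak_amp,
                            "trough_pos": trough_pos,
                            "trough_amp": trough_amp,
                            "peak_width": w_p, "trough_width": w_t}}
    profile = ShellProfile(edges=edges, n=n, n_prime=n_prime,
                           shell_density=shell_density, rho=rho,
                           provenance={"fixture": "shell_profile",
                                       "seed": seed})
    return profile, truth
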