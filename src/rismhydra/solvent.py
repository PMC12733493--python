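"""Bulk-solvent stage: 1D site-site RISM (XRISM) for rigid water models.

The 3D solvation solver needs the bulk solvent's site-site susceptibility

    chi_ab(k) = omega_ab(k) + rho * h_ab(k)

where ``omega`` is the rigid-molecule intramolecular correlation and ``h``
the converged site-site total correlation of the neat liquid.  This module
solves the radial XRISM equations

    H(k) = [I - W(k) C(k) rho]^(-1) W(k) C(k) W(k)

coupled to a KH or HNC closure, with Ng-style renormalization of the
Coulomb long range: the pair potential is split as u = u_s + u_l with
u_l = q_a q_g erf(eta r)/r, whose Fourier transform is analytic, so the
transformed functions stay short-ranged and the k->0 divergence cancels
inside the matrix algebra.

All sites of a molecule are carried explicitly (water is a 3x3 problem,
O/H1/H2); equivalent sites are detected by identical (charge, LJ) and used
by the 3D stage to reduce the kernel.  Plain XRISM is solved, without a
dielectric-consistency correction, so the bulk dielectric constant of the
model is not imposed.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dst

from .errors import ConvergenceError, InvalidModelError
from .mdiis import Mdiis
from .units import COULOMB, kT

__all__ = [
    "SolventSite",
    "SolventModel",
    "RadialGrid",
    "SusceptibilityTable",
    "SOLVENT_CATALOGUE",
    "get_solvent_model",
    "build_intramolecular",
    "solve_rism1d",
]

#: Conventional ambient state point: 298.15 K and 0.997 g/cm^3 water,
#: i.e. 0.03332 molecules per cubic Angstrom.
AMBIENT_TEMPERATURE = 298.15
AMBIENT_WATER_DENSITY = 0.03332


@dataclass(frozen=True)
class SolventSite:
    """One interaction site of a rigid solvent molecule.

    ``position`` is given in the molecular frame (Angstrom); ``charge`` in e,
    ``sigma`` (LJ diameter) in Angstrom, ``epsilon`` (LJ well depth) in
    kcal/mol.
    """

    name: str
    charge: float
    sigma: float
    epsilon: float
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.sigma < 0 or self.epsilon < 0:
            raise InvalidModelError(
                f"site {self.name}: sigma and epsilon must be >= 0")


@dataclass(frozen=True)
class SolventModel:
    """A rigid multi-site solvent at a fixed state point.

    ``density`` is the molecular number density in A^-3.  Every physical
    site appears once in ``sites`` (equivalent hydrogens are two entries);
    ``multiplicities`` maps a site name to the number of entries sharing it.
    """

    name: str
    sites: tuple[SolventSite, ...]
    density: float
    temperature: float

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidModelError("density must be positive")
        if self.temperature <= 0:
            raise InvalidModelError("temperature must be positive")
        total_q = sum(s.charge for s in self.sites)
        if abs(total_q) > 1e-10:
            raise InvalidModelError(
                f"per-molecule charge must sum to 0, got {total_q:.3e} e")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def multiplicities(self) -> dict[str, int]:
        mult: dict[str, int] = {}
        for s in self.sites:
            mult[s.name] = mult.get(s.name, 0) + 1
        return mult

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    @property
    def unique_site_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sites:
            if s.name not in seen:
                seen.append(s.name)
        return tuple(seen)

    def distance_matrix(self) -> np.ndarray:
        pos = np.array([s.position for s in self.sites], dtype=float)
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))


def _water_geometry(l_oh: float = 1.0, angle_deg: float = 109.47):
    """O at origin, two H at bond length ``l_oh`` opening ``angle_deg``."""
    half = np.deg2rad(angle_deg) / 2.0
    return (
        (0.0, 0.0, 0.0),
        (l_oh * np.sin(half), 0.0, l_oh * np.cos(half)),
        (-l_oh * np.sin(half), 0.0, l_oh * np.cos(half)),
    )


def _make_spce(name: str, sigma_h: float, epsilon_h: float) -> SolventModel:
    o, h1, h2 = _water_geometry()
    return SolventModel(
        name=name,
        sites=(
            SolventSite("Ow", -0.8476, 3.166, 0.1553, o),
            SolventSite("Hw", +0.4238, sigma_h, epsilon_h, h1),
            SolventSite("Hw", +0.4238, sigma_h, epsilon_h, h2),
        ),
        density=AMBIENT_WATER_DENSITY,
        temperature=AMBIENT_TEMPERATURE,
    )


#: Built-in rigid water models.  ``spce`` is the standard parameterization
#: (bare hydrogens).  ``mspce`` is the modified SPC/E commonly used with
#: integral-equation theories: small Lennard-Jones terms on the hydrogens
#: regularize the site equations where a bare Coulomb hydrogen would make
#: them singular.
SOLVENT_CATALOGUE: dict[str, SolventModel] = {
    "spce": _make_spce("spce", 0.0, 0.0),
    "mspce": _make_spce("mspce", 1.1657, 0.01553),
}


def get_solvent_model(name: str) -> SolventModel:
    try:
        return SOLVENT_CATALOGUE[name.lower()]
    except KeyError:
        raise InvalidModelError(
            f"unknown solvent model {name!r}; available: "
            f"{sorted(SOLVENT_CATALOGUE)}") from None


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid and its sine-transform conjugate.

    r_j = (j+1) dr for j = 0..n-1 and k_n = (n+1) dk with
    dk = pi / ((n_points+1) dr), the natural abscissae of the type-I
    discrete sine transform, so forward and inverse radial Fourier
    transforms are exact inverses on the grid.
    """

    n_points: int = 8192
    dr: float = 0.01

    def __post_init__(self):
        if self.dr <= 0:
            raise InvalidModelError("dr must be positive")
        if self.n_points < 8:
            raise InvalidModelError("n_points must be at least 8")

    @property
    def r(self) -> np.ndarray:
        return self.dr * np.arange(1, self.n_points + 1)

    @property
    def dk(self) -> float:
        return np.pi / ((self.n_points + 1) * self.dr)

    @property
    def k(self) -> np.ndarray:
        return self.dk * np.arange(1, self.n_points + 1)

    def fourier(self, f_r: np.ndarray) -> np.ndarray:
        """Radial 3D Fourier transform f(k) = 4 pi/k int r f sin(kr) dr."""
        return 4.0 * np.pi * self.dr * dst(self.r * f_r, type=1, axis=-1) / (2.0 * self.k)

    def inverse(self, f_k: np.ndarray) -> np.ndarray:
        """Inverse transform f(r) = 1/(2 pi^2 r) int k f(k) sin(kr) dk."""
        return self.dk * dst(self.k * f_k, type=1, axis=-1) / (4.0 * np.pi ** 2 * self.r)


def build_intramolecular(model: SolventModel, grid: RadialGrid) -> np.ndarray:
    """Intramolecular correlation omega_ag(k) of the rigid molecule.

    omega is sinc(k l_ag) for distinct sites at fixed separation l_ag and
    exactly 1 on the diagonal; the k->0 limit of sinc is 1 analytically.
    Returns an array of shape ``(n_k, n_sites, n_sites)``.
    """
    dists = model.distance_matrix()
    n = model.n_sites
    off_diagonal = ~np.eye(n, dtype=bool)
    if np.any(dists[off_diagonal] <= 0.0):
        raise InvalidModelError(
            "distinct sites with zero intramolecular distance")
    k = grid.k
    omega = np.empty((grid.n_points, n, n))
    for a in range(n):
        for g in range(n):
            if a == g:
                omega[:, a, g] = 1.0
            else:
                x = k * dists[a, g]
                omega[:, a, g] = np.sin(x) / x
    return omega


@dataclass
class SusceptibilityTable:
    """Solvent input of the 3D-RISM equation: chi_ab(k) = omega + rho h.

    ``chi`` and ``omega`` have shape ``(n_k, n_sites, n_sites)`` over the
    explicit sites of ``model``; ``rho_site`` holds the per-site number
    densities (each explicit site occurs once per molecule, so they all
    equal the molecular density).  ``h_r``/``g_r`` keep the real-space
    site-site correlations for inspection.
    """

    model: SolventModel
    grid: RadialGrid
    closure: str
    chi: np.ndarray
    omega: np.ndarray
    rho_site: np.ndarray
    h_r: np.ndarray | None = None
    c_r: np.ndarray | None = None
    residual: float | None = None
    n_iterations: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        asym = np.max(np.abs(self.chi - np.swapaxes(self.chi, 1, 2)))
        if asym > 1e-12:
            raise InvalidModelError(
                f"chi must be symmetric in its site indices (max asym {asym:.2e})")

    @property
    def k(self) -> np.ndarray:
        return self.grid.k

    def pair_distribution(self, i: int, j: int) -> np.ndarray:
        """g_ij(r) of the neat solvent for explicit site indices i, j."""
        if self.h_r is None:
            raise ValueError("real-space correlations were not stored")
        return 1.0 + self.h_r[:, i, j]

    def reduced_kernel(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Collapse equivalent sites for the 3D stage.

        Returns unique site names and the kernel K[k, u, v] such that
        h_v(k) = sum_u c_u(k) K[k, u, v], where u, v index unique sites and
        the sum over equivalent members of u has been absorbed into K.
        """
        names = self.model.site_names
        unique = self.model.unique_site_names
        members = {u: [i for i, n in enumerate(names) if n == u] for u in unique}
        rep = {u: members[u][0] for u in unique}
        nk = self.chi.shape[0]
        K = np.empty((nk, len(unique), len(unique)))
        for iu, u in enumerate(unique):
            for iv, v in enumerate(unique):
                K[:, iu, iv] = self.chi[:, members[u], rep[v]].sum(axis=1)
        return tuple(unique), K

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write a self-describing text table (k plus per-pair chi)."""
        names = self.model.site_names
        n = len(names)
        header = io.StringIO()
        header.write("rismhydra susceptibility table v1\n")
        header.write(f"model {self.model.name}\n")
        header.write(f"temperature_K {self.model.temperature!r}\n")
        header.write(f"density_A3 {self.model.density!r}\n")
        header.write(f"closure {self.closure}\n")
        header.write(f"n_points {self.grid.n_points}\n")
        header.write(f"dr_A {self.grid.dr!r}\n")
        header.write(f"sites {' '.join(names)}\n")
        cols = ["k"] + [f"chi_{names[i]}{i}_{names[j]}{j}"
                        for i in range(n) for j in range(i, n)]
        header.write("columns " + " ".join(cols))
        data = [self.k]
        for i in range(n):
            for j in range(i, n):
                data.append(self.chi[:, i, j])
        np.savetxt(path, np.column_stack(data), header=header.getvalue(),
                   fmt="%.12e")

    @staticmethod
    def load(path) -> "SusceptibilityTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line[1:].strip().split(None, 1)
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
        grid = RadialGrid(int(meta["n_points"]), float(meta["dr_A"]))
        model = get_solvent_model(meta["model"])
        model = dataclasses.replace(
            model, density=float(meta["density_A3"]),
            temperature=float(meta["temperature_K"]))
        raw = np.loadtxt(path)
        n = len(meta["sites"].split())
        chi = np.empty((grid.n_points, n, n))
        col = 1
        for i in range(n):
            for j in range(i, n):
                chi[:, i, j] = chi[:, j, i] = raw[:, col]
                col += 1
        omega = build_intramolecular(model, grid)
        return SusceptibilityTable(
            model=model, grid=grid, closure=meta.get("closure", "kh"),
            chi=chi, omega=omega,
            rho_site=np.full(n, model.density), meta=meta)


def _pair_potentials(model: SolventModel, grid: RadialGrid, eta: float,
                     charge_scale: float = 1.0):
    """Reduced short-range potential and analytic long-range k-space part.

    Returns (beta_u_short[r, a, g], beta_u_long_k[k, a, g]).
    """
    beta = 1.0 / kT(model.temperature)
    r = grid.r
    k = grid.k
    n = model.n_sites
    bus = np.empty((grid.n_points, n, n))
    bulk = np.empty((grid.n_points, n, n))
    from scipy.special import erfc
    for a, sa in enumerate(model.sites):
        for g, sg in enumerate(model.sites):
            sig = 0.5 * (sa.sigma + sg.sigma)
            eps = np.sqrt(sa.epsilon * sg.epsilon)
            u = np.zeros_like(r)
            if eps > 0 and sig > 0:
                sr6 = (sig / r) ** 6
                u = 4.0 * eps * (sr6 ** 2 - sr6)
            qq = charge_scale ** 2 * sa.charge * sg.charge * COULOMB
            u = u + qq * erfc(eta * r) / r
            bus[:, a, g] = beta * u
            bulk[:, a, g] = beta * qq * 4.0 * np.pi * np.exp(
                -k ** 2 / (4.0 * eta ** 2)) / k ** 2
    return bus, bulk


def _apply_closure(closure: str, d: np.ndarray) -> np.ndarray:
    """g as a function of d = -beta u + h - c."""
    if closure == "kh":
        return np.where(d <= 0.0, np.exp(np.minimum(d, 0.0)), 1.0 + d)
    if closure == "hnc":
        return np.exp(np.minimum(d, 100.0))
    raise ValueError(f"unknown closure {closure!r}; use 'kh' or 'hnc'")


def solve_rism1d(model: SolventModel, grid: RadialGrid | None = None,
                 closure: str = "kh", *, tolerance: float = 1e-8,
                 max_iterations: int = 20000, n_vectors: int = 20,
                 damping: float = 0.5, eta: float = 1.0,
                 charge_ladder: tuple[float, ...] = (0.0, 0.5, 0.75, 1.0),
                 store_h: bool = True) -> SusceptibilityTable:
    """Solve the neat-solvent XRISM equations and assemble chi_ab(k).

    Iterates on the renormalized indirect correlation
    t_s = h - c - beta u_l, so every transformed function is short-ranged.
    Convergence is judged on the max-norm change of t_s.  To reach the
    strongly charged water state point from scratch the solute charges are
    ramped along ``charge_ladder``, each rung warm-started from the last.

    Parameters mirror common 3D-RISM practice; the default tolerance is
    tighter than the 3D stage so the susceptibility error never dominates.
    """
    closure = closure.lower()
    if closure not in ("kh", "hnc"):
        raise ValueError(f"closure must be 'kh' or 'hnc', got {closure!r}")
    if grid is None:
        grid = RadialGrid()

    n = model.n_sites
    omega = build_intramolecular(model, grid)
    rho = model.density
    has_charges = any(abs(s.charge) > 0 for s in model.sites)
    ladder = tuple(charge_ladder) if has_charges else (1.0,)

    t_s = np.zeros((grid.n_points, n, n))
    eye = np.eye(n)
    trace: list[float] = []
    total_iter = 0

    for scale in ladder:
        beta_us, beta_ulk = _pair_potentials(model, grid, eta, scale)
        accel = Mdiis(n_vectors=n_vectors, damping=damping)
        converged = False
        for _ in range(max_iterations):
            d = -beta_us + t_s
            g = _apply_closure(closure, d)
            h = g - 1.0
            c_s = h - t_s
            c_s_k = grid.fourier(np.moveaxis(c_s, 0, -1))
            c_s_k = np.moveaxis(c_s_k, -1, 0)
            c_k = c_s_k - beta_ulk
            # H = (I - W C rho)^-1 W C W, batched over k
            wc = omega @ c_k
            h_k = np.linalg.solve(eye[None] - rho * wc, wc @ omega)
            h_k = 0.5 * (h_k + np.swapaxes(h_k, 1, 2))
            t_s_k = h_k - c_k - beta_ulk  # = h - c - beta u_l in k-space
            t_s_new = grid.inverse(np.moveaxis(t_s_k, 0, -1))
            t_s_new = np.moveaxis(t_s_new, -1, 0)
            res = t_s_new - t_s
            res_norm = float(np.max(np.abs(res)))
            trace.append(res_norm)
            total_iter += 1
            if not np.isfinite(res_norm):
                raise ConvergenceError(
                    f"1D RISM diverged (non-finite residual) at charge "
                    f"scale {scale}", residual=res_norm, trace=trace)
            if res_norm < tolerance:
                converged = True
                break
            t_s = accel.step(t_s, res).reshape(t_s.shape)
            t_s = 0.5 * (t_s + np.swapaxes(t_s, 1, 2))
        if not converged:
            raise ConvergenceError(
                f"1D RISM did not converge within {max_iterations} "
                f"iterations at charge scale {scale} "
                f"(last residual {trace[-1]:.3e})",
                residual=trace[-1], trace=trace)

    # Final consistent fields at full charge
    beta_us, beta_ulk = _pair_potentials(model, grid, eta, ladder[-1])
    d = -beta_us + t_s
    g = _apply_closure(closure, d)
    h = g - 1.0
    c_s = h - t_s
    c_s_k = np.moveaxis(grid.fourier(np.moveaxis(c_s, 0, -1)), -1, 0)
    c_k = c_s_k - beta_ulk
    wc = omega @ c_k
    h_k = np.linalg.solve(eye[None] - rho * wc, wc @ omega)
    h_k = 0.5 * (h_k + np.swapaxes(h_k, 1, 2))

    chi = omega + rho * h_k
    chi = 0.5 * (chi + np.swapaxes(chi, 1, 2))
    # full direct correlation in real space: c = h - t, t = t_s + beta u_l
    from scipy.special import erf
    r = grid.r
    beta = 1.0 / kT(model.temperature)
    beta_ul_r = np.empty_like(t_s)
    for a, sa in enumerate(model.sites):
        for gi, sg in enumerate(model.sites):
            qq = ladder[-1] ** 2 * sa.charge * sg.charge * COULOMB
            beta_ul_r[:, a, gi] = beta * qq * erf(eta * r) / r
    c_full = h - t_s - beta_ul_r
    return SusceptibilityTable(
        model=model, grid=grid, closure=closure, chi=chi, omega=omega,
        rho_site=np.full(n, rho), h_r=(h if store_h else None),
        c_r=(c_full if store_h else None),
        residual=trace[-1] if trace else 0.0, n_iterations=total_iter,
        meta={"eta": eta, "tolerance": tolerance})
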