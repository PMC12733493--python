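"""Solute-solvent interaction potentials on the 3D grid.

The solute-site potential is the usual LJ + Coulomb site sum with
Lorentz-Berthelot combining (arithmetic sigma, geometric epsilon).  The
Coulomb part is Ng-split: the erfc-damped short range is tabulated on the
grid together with the LJ term, while the erf complement lives analytically
in reciprocal space (see :func:`coulomb_long_k`), which removes the slowly
decaying real-space tail from the FFTs and keeps the iteration stable.

Potentials are stored in kT units, capped inside hard cores so the closure
exponential never sees an infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfc

from .grid import GridSpec
from .solvent import SolventSite
from .units import COULOMB, kT

__all__ = ["PotentialField", "build_potential", "choose_eta",
           "coulomb_long_k", "coulomb_long_real"]

#: Hard-core cap on the reduced short-range potential; exp(-40) underflows
#: gracefully and avoids inf - inf in the closure.
DEFAULT_CORE_CAP = 40.0


@dataclass
class PotentialField:
    """Short-range reduced potential plus long-range bookkeeping.

    ``u_short`` is -beta-reduced (kT units) on the grid; the long-range
    Coulomb part is not tabulated here — the solver reconstructs it in
    reciprocal space from the solute charges, ``eta`` and ``site_charge``.
    """

    u_short: np.ndarray
    grid: GridSpec
    site_charge: float
    eta: float
    beta: float
    cap: float = DEFAULT_CORE_CAP


def choose_eta(grid: GridSpec) -> float:
    """Ewald-style splitting parameter from the box size.

    erfc(eta r) must be negligible at half the smallest box length so the
    tabulated short range does not wrap around the periodic images.
    """
    r_half = 0.5 * float(np.min(grid.lengths))
    return max(0.25, 4.0 / r_half)


def build_potential(solute, site: SolventSite, grid: GridSpec,
                    temperature: float, eta: float | None = None,
                    cap: float = DEFAULT_CORE_CAP) -> PotentialField:
    """Tabulate u_short for one solvent site, in kT units.

    u_short = sum_atoms [ 4 eps_c ((sig_c/r)^12 - (sig_c/r)^6)
                          + q_site q_atom erfc(eta r)/r ]
    capped at ``cap`` kT.  Grid points coincident with an atom centre get
    the capped core value, never NaN/inf.
    """
    if eta is None:
        eta = choose_eta(grid)
    beta = 1.0 / kT(temperature)
    pts = grid.points()
    u = np.zeros(grid.n_points)
    for pos, q, sig_a, eps_a in zip(solute.positions, solute.charges,
                                    solute.sigmas, solute.epsilons):
        r = np.linalg.norm(pts - pos, axis=1)
        r = np.maximum(r, 1e-6)
        sig = 0.5 * (sig_a + site.sigma)
        eps = np.sqrt(eps_a * site.epsilon)
        if eps > 0.0 and sig > 0.0:
            sr6 = (sig / r) ** 6
            u += 4.0 * eps * (sr6 * sr6 - sr6)
        qq = q * site.charge * COULOMB
        if qq != 0.0:
            u += qq * erfc(eta * r) / r
    u = np.minimum(beta * u, cap)
    return PotentialField(u_short=u.reshape(grid.shape), grid=grid,
                          site_charge=site.charge, eta=eta, beta=beta,
                          cap=cap)


def coulomb_long_k(solute, grid: GridSpec, eta: float) -> np.ndarray:
    """Reciprocal-space long-range electrostatic potential of the solute.

    Returns phi_l(k) on the rfftn lattice, in (kcal/mol)/e per unit charge,
    on the *continuous*-transform scale (divide by the voxel volume to land
    on DFT scale):

        phi_l(k) = C sum_i q_i exp(-i k.(r_i - origin)) 4 pi
                   exp(-k^2/(4 eta^2)) / k^2

    The k = 0 term is dropped, which for a net-charged solute amounts to a
    uniform neutralizing background.
    """
    (kx, ky, kz), kmag = grid.k_lattice()
    origin = np.array(grid.origin)
    structure = np.zeros(kmag.shape, dtype=complex)
    for pos, q in zip(solute.positions, solute.charges):
        d = pos - origin
        phase = kx * d[0] + ky * d[1] + kz * d[2]
        structure += q * np.exp(-1j * phase)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 4.0 * np.pi * np.exp(-kmag ** 2 / (4.0 * eta ** 2)) / kmag ** 2
    kernel[kmag == 0.0] = 0.0
    return COULOMB * structure * kernel


def coulomb_long_real(solute, points: np.ndarray, eta: float) -> np.ndarray:
    """Direct real-space evaluation of the erf-damped long-range potential.

    phi_l(r) = C sum_i q_i erf(eta |r - r_i|)/|r - r_i|, in (kcal/mol)/e.
    Serves as the summation oracle for the reciprocal-space representation.
    """
    points = np.atleast_2d(points)
    phi = np.zeros(len(points))
    for pos, q in zip(solute.positions, solute.charges):
        r = np.linalg.norm(points - pos, axis=1)
        r = np.maximum(r, 1e-12)
        phi += q * erf(eta * r) / r
    return COULOMB * phi
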