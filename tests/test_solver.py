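"""3D solver: closure branches, OZ convolution oracles, iteration scheme."""

import itertools

import numpy as np
import pytest
from scipy.fft import irfftn, rfftn

from rismhydra.errors import ConvergenceError, InvalidModelError
from rismhydra.grid import GridSpec, build_grid
from rismhydra.mdiis import Mdiis
from rismhydra.solver import (boundary_deviation, hnc_closure,
                              interpolate_kernel, kh_closure, oz_convolve,
                              solve_3drism)


def angular_anisotropy(g, grid, r_lo=2.4, r_hi=9.4, window=0.4, step=0.2):
    """Angular spread of a field around a single atom at the origin.

    For overlapping thin radial shells, remove the radial trend with a
    local cubic fit and take the standard deviation of the remainder (the
    spread of g over directions at fixed radius); the radial variation is
    the range of the shell means.  Returns (max spread, variation).
    """
    r = np.linalg.norm(grid.points(), axis=1)
    gv = np.asarray(g).ravel()
    spread = 0.0
    means = []
    for lo in np.arange(r_lo, r_hi, step):
        m = (r >= lo) & (r < lo + window)
        if m.sum() < 12:
            continue
        coef = np.polyfit(r[m], gv[m], 3)
        resid = gv[m] - np.polyval(coef, r[m])
        spread = max(spread, float(resid.std()))
        means.append(gv[m].mean())
    return spread, float(max(means) - min(means))


class TestKhClosure:
    def test_zero_fields_give_bulk(self):
        g, c = kh_closure(np.zeros(4), np.zeros(4), np.zeros(4))
        assert np.all(g == 1.0)
        assert np.all(c == 0.0)

    def test_capped_core_is_excluded_volume(self):
        g, _ = kh_closure(np.array([40.0]), np.array([0.0]), np.array([0.0]))
        assert g[0] == pytest.approx(np.exp(-40.0))

    def test_scalar_evaluation(self):
        # u/kT = 1.0, h = 0.2, c = 0.1 -> d = -0.9, depleted branch
        g, c_new = kh_closure(np.array([1.0]), np.array([0.2]),
                              np.array([0.1]))
        assert g[0] == pytest.approx(np.exp(-0.9))
        assert c_new[0] == pytest.approx(np.exp(-0.9) - 1.0 - 0.1)

    def test_branch_continuity_value_and_slope(self):
        # exp and linear branches meet at d = 0 with matching value/slope
        eps = 1e-9
        u = np.array([0.0, 0.0])
        h = np.array([-eps, +eps])
        c = np.zeros(2)
        g, _ = kh_closure(u, h, c)
        assert abs(g[1] - g[0]) == pytest.approx(2 * eps, rel=1e-4)
        assert g.mean() == pytest.approx(1.0, abs=1e-8)

    def test_enhanced_branch_is_linear(self):
        g, _ = kh_closure(np.array([0.0]), np.array([2.5]), np.array([0.0]))
        assert g[0] == pytest.approx(3.5)

    def test_hnc_exponential_everywhere(self):
        g, _ = hnc_closure(np.array([0.0]), np.array([0.5]), np.array([0.0]))
        assert g[0] == pytest.approx(np.exp(0.5))


def smooth_kernel(grid, n_sites=2):
    """Synthetic smooth dimensionless kernel on the rfft lattice."""
    _, kmag = grid.k_lattice()
    K = np.empty((n_sites, n_sites, *kmag.shape))
    for u in range(n_sites):
        for v in range(n_sites):
            K[u, v] = (1.0 + 0.3 * (u + v)) * np.exp(-0.5 * kmag ** 2)
    return K


class TestOzConvolve:
    def test_zero_c_gives_zero_h(self):
        grid = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (8, 8, 8))
        c = np.zeros((2, 8, 8, 8))
        h = oz_convolve(c, smooth_kernel(grid))
        assert np.all(h == 0.0)

    def test_identity_kernel_returns_c(self, rng):
        grid = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (8, 8, 8))
        _, kmag = grid.k_lattice()
        K = np.zeros((2, 2, *kmag.shape))
        K[0, 0] = K[1, 1] = 1.0
        c = rng.normal(size=(2, 8, 8, 8))
        h = oz_convolve(c, K)
        assert np.allclose(h, c, atol=1e-12)

    def test_matches_direct_real_space_convolution(self, rng):
        # brute-force O(N^2) circular convolution with the kernel's
        # real-space image
        grid = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (8, 8, 8))
        K = smooth_kernel(grid)
        c = rng.normal(size=(2, 8, 8, 8))
        h_fft = oz_convolve(c, K)
        h_direct = np.zeros_like(h_fft)
        k_real = np.array([[irfftn(K[u, v], s=(8, 8, 8))
                            for v in range(2)] for u in range(2)])
        for u, v in itertools.product(range(2), repeat=2):
            for sx, sy, sz in itertools.product(range(8), repeat=3):
                h_direct[v] += (c[u, sx, sy, sz] *
                                np.roll(k_real[u, v], (sx, sy, sz),
                                        axis=(0, 1, 2)))
        scale = np.abs(h_fft).max()
        assert np.max(np.abs(h_fft - h_direct)) / scale < 1e-10

    def test_short_susceptibility_k_range_rejected(self, chi_mspce):
        # a 0.005 A grid needs k out to ~1088/A, far beyond the table
        grid = GridSpec((0.0, 0.0, 0.0), (0.005, 0.005, 0.005), (8, 8, 8))
        with pytest.raises(InvalidModelError, match="Nyquist"):
            interpolate_kernel(chi_mspce, grid)


class TestMdiis:
    def test_reduces_to_damped_picard_with_one_vector(self):
        accel = Mdiis(n_vectors=1, damping=0.4)
        x = np.array([1.0, 2.0])
        r = np.array([0.5, -0.5])
        out = accel.step(x, r)
        assert np.allclose(out, x + 0.4 * r)

    def test_solves_linear_fixed_point_faster_than_picard(self, rng):
        # x* = A x + b with spectral radius ~0.95: MDIIS accelerates
        n = 40
        Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        A = Q @ np.diag(rng.uniform(-0.95, 0.95, n)) @ Q.T
        b = rng.normal(size=n)

        def run(n_vectors, iters):
            accel = Mdiis(n_vectors=n_vectors, damping=1.0)
            x = np.zeros(n)
            for _ in range(iters):
                r = A @ x + b - x
                if np.max(np.abs(r)) < 1e-12:
                    return x, True
                x = accel.step(x, r)
            return x, False

        x_mdiis, ok = run(8, 200)
        assert ok
        x_ref = np.linalg.solve(np.eye(n) - A, b)
        assert np.allclose(x_mdiis, x_ref, atol=1e-10)
        _, picard_ok = run(1, 200)
        assert not picard_ok  # plain iteration is still far at 200 steps

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Mdiis(n_vectors=0)
        with pytest.raises(ValueError):
            Mdiis(damping=1.5)


class TestSolve3d:
    def test_converges_below_tolerance(self, lj_fields):
        assert lj_fields.converged
        assert lj_fields.residual < 1e-6

    def test_distributions_non_negative(self, lj_fields, ion_fields):
        for fields in (lj_fields, ion_fields):
            for name in fields.site_names:
                assert fields.g[name].min() >= 0.0

    def test_bulk_recovered_at_box_boundary(self, lj_fields, ion_fields):
        for fields in (lj_fields, ion_fields):
            for name in fields.site_names:
                assert boundary_deviation(fields.g[name]) < 1e-2

    def test_converged_state_is_a_fixed_point(self, chi_mspce, lj_solute,
                                              lj_grid, lj_fields):
        # one more OZ/closure application starting from the converged c
        # changes it by less than 10x the residual tolerance
        from rismhydra.potential import build_potential
        c0 = np.stack([lj_fields.c_short[n] for n in lj_fields.site_names])
        _, kernel = interpolate_kernel(chi_mspce, lj_grid)
        h = oz_convolve(c0, kernel)
        t = h - c0
        site = {s.name: s for s in chi_mspce.model.sites}
        eta = lj_fields.provenance["eta"]
        us = np.stack([build_potential(lj_solute, site[n], lj_grid,
                                       chi_mspce.model.temperature,
                                       eta=eta).u_short
                       for n in lj_fields.site_names])
        g, c_new = kh_closure(us, t + c0, c0)
        assert np.max(np.abs(c_new - c0)) < 1e-5

    def test_mdiis_matches_damped_picard(self, chi_mspce, lj_solute,
                                         lj_grid, lj_fields):
        picard = solve_3drism(lj_solute, chi_mspce, lj_grid,
                              method="picard", damping=0.5,
                              max_iterations=5000, tolerance=1e-6)
        for name in lj_fields.site_names:
            dev = np.max(np.abs(lj_fields.g[name] - picard.g[name]))
            assert dev < 1e-5  # 10x the residual tolerance

    def test_two_initial_guesses_reach_same_solution(self, chi_mspce,
                                                     ion_solute,
                                                     ion_fields):
        alt = solve_3drism(ion_solute, chi_mspce, ion_fields.grid,
                           initial="zero", tolerance=1e-6)
        for name in ion_fields.site_names:
            dev = np.max(np.abs(ion_fields.g[name] - alt.g[name]))
            assert dev < 1e-5

    def test_spherical_symmetry_for_single_atom(self, lj_fields):
        spread, variation = angular_anisotropy(lj_fields.g["Ow"],
                                               lj_fields.grid)
        assert spread < 0.01 * variation

    def test_residual_decreases_monotonically_after_warmup(self, lj_fields):
        trace = np.array(lj_fields.trace)
        warmup = 5
        assert np.all(np.diff(trace[warmup:]) < 0)

    def test_divergence_error_carries_trace(self, chi_mspce, lj_solute,
                                            lj_grid):
        with pytest.raises(ConvergenceError) as err:
            solve_3drism(lj_solute, chi_mspce, lj_grid, max_iterations=3)
        assert len(err.value.trace) == 3
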