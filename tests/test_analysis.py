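"""Hydration analysis: distances, shell profiles, counts, H-bonds, SASA."""

import numpy as np
import pytest

from rismhydra.analysis import (PocketSpec, distance_transform,
                                find_shell_boundary, hbond_fraction,
                                hydration_number, pocket_hydration, sasa,
                                shell_profile, sphere_points)
from rismhydra.errors import (InvalidModelError, NoBoundaryError,
                              RismHydraError)
from rismhydra.fixtures import (FixtureRecipe, make_shell_profile,
                                make_toy_solute, paint_radial_field,
                                two_gaussian_profile)
from rismhydra.grid import GridSpec, build_grid
from rismhydra.solute import SoluteAtom, SoluteSystem

RHO = 0.03332


def atom_at(pos, serial=1, res_num=1, name="C", radius=1.7):
    return SoluteAtom(serial, name, name[0], "TOY", res_num, "A",
                      tuple(pos), 0.0, 3.4, 0.1, radius)


@pytest.fixture(scope="module")
def single_atom_setup():
    solute = make_toy_solute(FixtureRecipe("lj_sphere"))
    grid = build_grid(solute, buffer=12.0, spacing=0.4)
    dist = distance_transform(solute, grid)
    return solute, grid, dist


class TestDistanceTransform:
    def test_single_atom_on_grid_node(self):
        solute = SoluteSystem([atom_at((0.0, 0.0, 0.0))])
        grid = GridSpec((-2.0, -2.0, -2.0), (1.0, 1.0, 1.0), (5, 5, 5))
        dist = distance_transform(solute, grid)
        assert dist.values[2, 2, 2] == 0.0
        assert dist.values[3, 2, 2] == pytest.approx(1.0)
        assert dist.values[2, 1, 2] == pytest.approx(1.0)

    def test_two_atoms_pointwise_minimum(self):
        a = SoluteSystem([atom_at((0.0, 0.0, 0.0))])
        b = SoluteSystem([atom_at((3.0, 0.0, 0.0))])
        both = SoluteSystem([atom_at((0.0, 0.0, 0.0)),
                             atom_at((3.0, 0.0, 0.0), serial=2)])
        grid = GridSpec((-2.0, -2.0, -2.0), (0.5, 0.5, 0.5), (14, 8, 8))
        da = distance_transform(a, grid).values
        db = distance_transform(b, grid).values
        dboth = distance_transform(both, grid).values
        assert np.allclose(dboth, np.minimum(da, db))

    def test_matches_brute_force_all_pairs(self, rng):
        solute = make_toy_solute(FixtureRecipe("polyatomic_random",
                                               {"n": 10}, seed=5))
        grid = build_grid(solute, buffer=4.0, spacing=1.0)
        dist = distance_transform(solute, grid)
        pts = grid.points()
        brute = np.min(np.linalg.norm(
            pts[:, None, :] - solute.positions[None, :, :], axis=2), axis=1)
        assert np.allclose(dist.values.ravel(), brute, atol=1e-12)

    def test_lipschitz_along_axes(self, single_atom_setup):
        _, grid, dist = single_atom_setup
        for axis in range(3):
            jump = np.abs(np.diff(dist.values, axis=axis))
            assert jump.max() <= grid.spacing[axis] + 1e-12

    def test_vdw_surface_variant_subtracts_radius(self):
        solute = SoluteSystem([atom_at((0.0, 0.0, 0.0), radius=1.5)])
        grid = GridSpec((-4.0, -4.0, -4.0), (1.0, 1.0, 1.0), (9, 9, 9))
        centre = distance_transform(solute, grid, "vdw-surface")
        assert centre.values[8, 4, 4] == pytest.approx(4.0 - 1.5)
        assert centre.values[4, 4, 4] == 0.0  # clamped inside the core


class TestShellProfile:
    def test_bulk_limit(self, single_atom_setup):
        solute, grid, dist = single_atom_setup
        g = np.ones(grid.shape)
        prof = shell_profile(g, dist, RHO)
        centers = prof.centers
        ok = np.isfinite(prof.shell_density)
        assert np.allclose(prof.shell_density[ok], 1.0, atol=1e-12)
        # n(r_cut) = rho |V(r_cut)| (a counting identity for g = 1)
        v_meas = prof.n[-1] / RHO
        assert v_meas == pytest.approx(grid.n_points * grid.voxel_volume,
                                       rel=1e-12)

    def test_vacuum(self, single_atom_setup):
        _, grid, dist = single_atom_setup
        prof = shell_profile(np.zeros(grid.shape), dist, RHO)
        assert np.all(prof.n == 0.0)
        assert np.all(prof.n_prime == 0.0)

    def test_painted_two_gaussian_matches_1d_quadrature(self):
        from scipy.integrate import quad
        solute = make_toy_solute(FixtureRecipe("lj_sphere"))
        grid = build_grid(solute, buffer=10.0, spacing=0.25)
        dist = distance_transform(solute, grid)
        profile = two_gaussian_profile()
        field = paint_radial_field(profile, solute, grid, dist)
        r_cut = 6.0
        n_grid = hydration_number(field, dist, r_cut, RHO)
        oracle, _ = quad(lambda s: profile(s) * 4 * np.pi * s ** 2 * RHO,
                         0.0, r_cut)
        assert n_grid == pytest.approx(oracle, rel=0.01)

    def test_n_nondecreasing_and_zero_at_origin(self, single_atom_setup):
        solute, grid, dist = single_atom_setup
        field = paint_radial_field(two_gaussian_profile(), solute, grid,
                                   dist)
        prof = shell_profile(field, dist, RHO)
        assert prof.n[0] == 0.0
        assert np.all(np.diff(prof.n) >= 0.0)

    def test_bin_below_spacing_rejected(self, single_atom_setup):
        _, grid, dist = single_atom_setup
        with pytest.raises(InvalidModelError):
            shell_profile(np.ones(grid.shape), dist, RHO, bin_width=0.1)


class TestShellBoundary:
    def test_recovers_constructed_trough(self, single_atom_setup):
        solute, grid, dist = single_atom_setup
        field = paint_radial_field(two_gaussian_profile(trough_pos=4.0),
                                   solute, grid, dist)
        prof = shell_profile(field, dist, RHO)
        r_star, weak = find_shell_boundary(prof)
        assert abs(r_star - 4.0) <= prof.bin_width
        assert not weak

    def test_flat_profile_raises(self, single_atom_setup):
        _, grid, dist = single_atom_setup
        prof = shell_profile(np.ones(grid.shape), dist, RHO)
        with pytest.raises(NoBoundaryError):
            find_shell_boundary(prof)

    def test_synthetic_profiles_recover_troughs(self):
        hits = 0
        for seed in range(50):
            prof, truth = make_shell_profile(seed)
            r_star, _ = find_shell_boundary(prof)
            if abs(r_star - truth["trough_pos"]) <= prof.bin_width:
                hits += 1
        assert hits >= 49

    def test_weak_shell_flagged(self):
        # a genuine local minimum that never dips below bulk density
        from rismhydra.analysis import ShellProfile
        edges = 0.1 * np.arange(101)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = (1.0 + 0.8 * np.exp(-(centers - 2.8) ** 2 / 0.2)
                   + 0.3 * np.exp(-(centers - 5.5) ** 2 / 0.5))
        vol = 4 * np.pi * centers ** 2
        n_prime = RHO * density * vol
        n = np.concatenate([[0.0], np.cumsum(n_prime) * 0.1])
        prof = ShellProfile(edges=edges, n=n, n_prime=n_prime,
                            shell_density=density, rho=RHO)
        with pytest.warns(UserWarning, match="weak"):
            r_star, weak = find_shell_boundary(prof)
        assert weak
        assert 3.0 < r_star < 5.0


class TestHydrationNumber:
    def test_bulk_sphere_volume(self, single_atom_setup):
        solute, grid, dist = single_atom_setup
        n = hydration_number(np.ones(grid.shape), dist, 5.0, RHO)
        assert n == pytest.approx(RHO * 4 / 3 * np.pi * 5 ** 3, rel=0.02)

    def test_monotone_in_r_cut(self, single_atom_setup):
        solute, grid, dist = single_atom_setup
        field = paint_radial_field(two_gaussian_profile(), solute, grid,
                                   dist)
        values = [hydration_number(field, dist, rc, RHO)
                  for rc in np.arange(1.0, 10.0, 0.5)]
        assert np.all(np.diff(values) >= 0.0)

    def test_out_of_range_r_cut_rejected(self, single_atom_setup):
        _, grid, dist = single_atom_setup
        with pytest.raises(RismHydraError):
            hydration_number(np.ones(grid.shape), dist, 1e3, RHO)

    def test_grid_refinement_changes_little(self):
        solute = make_toy_solute(FixtureRecipe("lj_sphere"))
        values = []
        for spacing in (0.5, 0.25):
            grid = build_grid(solute, buffer=10.0, spacing=spacing)
            dist = distance_transform(solute, grid)
            field = paint_radial_field(two_gaussian_profile(), solute,
                                       grid, dist)
            values.append(hydration_number(field, dist, 6.0, RHO))
        assert abs(values[1] - values[0]) / values[1] < 0.01


@pytest.fixture(scope="module")
def pocket_setup():
    atoms = [atom_at((0.0, 0.0, 0.0), 1, res_num=1),
             atom_at((4.0, 0.0, 0.0), 2, res_num=2),
             atom_at((0.0, 4.0, 0.0), 3, res_num=3)]
    solute = SoluteSystem(atoms)
    grid = build_grid(solute, buffer=9.0, spacing=0.5)
    dist = distance_transform(solute, grid)
    field = paint_radial_field(two_gaussian_profile(), solute, grid, dist)
    return solute, dist, field


class TestPocketHydration:
    def test_full_partition_recovers_total(self, pocket_setup):
        solute, dist, field = pocket_setup
        r_cut = 4.5
        n_tot = hydration_number(field, dist, r_cut, RHO)
        everything = PocketSpec("all", tuple(
            (name, num) for _, num, name in solute.residues))
        assert pocket_hydration(field, dist, solute, everything, r_cut,
                                RHO) == pytest.approx(n_tot, abs=1e-10)

    def test_disjoint_pockets_sum_to_total(self, pocket_setup):
        solute, dist, field = pocket_setup
        r_cut = 4.5
        n_tot = hydration_number(field, dist, r_cut, RHO)
        parts = [pocket_hydration(field, dist, solute,
                                  PocketSpec(f"p{num}", (("TOY", num),)),
                                  r_cut, RHO)
                 for num in (1, 2, 3)]
        assert sum(parts) == pytest.approx(n_tot, abs=1e-10)

    def test_absent_residue_named_in_error(self, pocket_setup):
        solute, dist, field = pocket_setup
        with pytest.raises(RismHydraError, match="GLY"):
            pocket_hydration(field, dist, solute,
                             PocketSpec("bad", (("GLY", 99),)), 4.5, RHO)


class TestHbondFraction:
    def test_apolar_solute_gives_zero(self, single_atom_setup):
        solute, grid, dist = single_atom_setup  # a pure LJ sphere (Ar)
        ones = np.ones(grid.shape)
        with pytest.warns(UserWarning, match="no polar"):
            frac = hbond_fraction(ones, ones, solute, dist, 5.0, 10.0, RHO)
        assert frac == 0.0

    def test_vacuum_fields_give_zero(self):
        atoms = [SoluteAtom(1, "O", "O", "TOY", 1, "A", (0.0, 0.0, 0.0),
                            -0.5, 3.0, 0.2, 1.5),
                 SoluteAtom(2, "H", "H", "TOY", 1, "A", (1.0, 0.0, 0.0),
                            0.5, 1.0, 0.02, 0.6)]
        solute = SoluteSystem(atoms)
        grid = build_grid(solute, buffer=8.0, spacing=0.5)
        dist = distance_transform(solute, grid)
        zeros = np.zeros(grid.shape)
        frac = hbond_fraction(zeros, zeros, solute, dist, 5.0, 10.0, RHO)
        assert frac == 0.0

    def test_fraction_clamped_with_warning(self):
        atoms = [SoluteAtom(1, "O", "O", "TOY", 1, "A", (0.0, 0.0, 0.0),
                            -0.5, 3.0, 0.2, 1.5)]
        solute = SoluteSystem(atoms)
        grid = build_grid(solute, buffer=8.0, spacing=0.5)
        dist = distance_transform(solute, grid)
        huge = 100.0 * np.ones(grid.shape)
        with pytest.warns(UserWarning, match="clamped"):
            frac = hbond_fraction(huge, huge, solute, dist, 5.0, 1.0, RHO)
        assert frac == 1.0


class TestSasa:
    def test_single_sphere(self):
        solute = SoluteSystem([atom_at((0.0, 0.0, 0.0), radius=1.6)])
        total, _ = sasa(solute, probe=1.4)
        assert total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.005)

    def test_far_separated_pair_is_additive(self):
        solute = SoluteSystem([atom_at((0.0, 0.0, 0.0), radius=1.6),
                               atom_at((20.0, 0.0, 0.0), 2, radius=1.6)])
        total, per_res = sasa(solute, probe=1.4)
        single = 4 * np.pi * 3.0 ** 2
        # additivity is exact: no quadrature point is occluded
        one, _ = sasa(SoluteSystem([atom_at((0.0, 0.0, 0.0), radius=1.6)]),
                      probe=1.4)
        assert total == pytest.approx(2 * one, abs=1e-9)
        assert total == pytest.approx(2 * single, rel=0.005)

    def test_overlapping_pair_matches_spherical_cap_formula(self):
        # two equal spheres R = r + probe = 3.1, centres d = 2.0 apart:
        # each loses a cap of height h = R - d/2
        r, probe, d = 1.7, 1.4, 2.0
        R = r + probe
        solute = SoluteSystem([atom_at((0.0, 0.0, 0.0), radius=r),
                               atom_at((d, 0.0, 0.0), 2, radius=r)])
        total, _ = sasa(solute, probe=probe)
        h = R - d / 2
        expected = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * h)
        assert total == pytest.approx(expected, rel=0.01)

    def test_quadrature_convergence(self):
        solute = make_toy_solute(FixtureRecipe("polyatomic_random",
                                               {"n": 8}, seed=2))
        a, _ = sasa(solute, n_points=960)
        b, _ = sasa(solute, n_points=1920)
        assert abs(a - b) / b < 0.003

    def test_matches_independent_shrake_rupley(self):
        # cross-check against biotite's implementation on a random solute
        import biotite.structure as struc
        solute = make_toy_solute(FixtureRecipe("polyatomic_random",
                                               {"n": 12}, seed=9))
        ours, _ = sasa(solute, probe=1.4, n_points=1920)
        arr = struc.AtomArray(len(solute))
        arr.coord = solute.positions
        arr.element = np.array(["C"] * len(solute))
        arr.res_id = np.ones(len(solute), dtype=int)
        arr.res_name = np.array(["TOY"] * len(solute))
        arr.atom_name = np.array([a.name for a in solute.atoms])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=1920,
                            vdw_radii=solute.vdw_radii.astype(
                                np.float32)).sum()
        assert ours == pytest.approx(theirs, rel=0.01)

    def test_sphere_points_unit_norm_and_deterministic(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.allclose(pts, sphere_points(960))
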