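"""Shared fixtures: solved solvent tables and converged toy fields.

The expensive stages (1D water solve, 3D toy solves) are session-scoped so
the whole suite pays for them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from rismhydra.fixtures import FixtureRecipe, make_toy_solute
from rismhydra.grid import build_grid
from rismhydra.solvent import RadialGrid, get_solvent_model, solve_rism1d
from rismhydra.solver import solve_3drism

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chi_mspce():
    """Converged modified-SPC/E water susceptibility on a test-size grid."""
    return solve_rism1d(get_solvent_model("mspce"), RadialGrid(2048, 0.02))


@pytest.fixture(scope="session")
def lj_solute():
    return make_toy_solute(FixtureRecipe("lj_sphere"))


@pytest.fixture(scope="session")
def lj_grid(lj_solute):
    return build_grid(lj_solute, buffer=14.0, spacing=0.5)


@pytest.fixture(scope="session")
def lj_fields(chi_mspce, lj_solute, lj_grid):
    """MDIIS-converged fields for a single neutral LJ sphere in water."""
    return solve_3drism(lj_solute, chi_mspce, lj_grid, tolerance=1e-6)


@pytest.fixture(scope="session")
def ion_solute():
    return make_toy_solute(FixtureRecipe("ion", {"q": -1.0}))


@pytest.fixture(scope="session")
def ion_fields(chi_mspce, ion_solute):
    grid = build_grid(ion_solute, buffer=14.0, spacing=0.5)
    return solve_3drism(ion_solute, chi_mspce, grid, tolerance=1e-6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
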