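import numpy as np
import pytest

from hembed.grid import GaussianSpec, deposit_gaussians, make_cubic_grid
from hembed.hierarchical import EmbeddingConfig, hierarchical_coupling
from hembed.synth import standard_md_system, standard_test_system


@pytest.fixture(scope="session")
def standard_system():
    """The seeded reference system shared by the battery."""
    return standard_test_system(seed=1)


@pytest.fixture(scope="session")
def alldirect_reference(standard_system):
    """All-direct (huge cutoff) coupling result for the standard system."""
    grid, qm, mm = standard_system
    cfg = EmbeddingConfig(cutoff=1e9, multipole_order=6)
    return hierarchical_coupling(grid, mm, qm, cfg)


@pytest.fixture(scope="session")
def md_system():
    return standard_md_system(seed=1)


@pytest.fixture(scope="session")
def unit_gaussian_grid():
    """A -1 e, width-1 Gaussian on a 64^3 grid of edge 16 bohr: quadrature
    errors are ~1e-15, so it doubles as an analytic oracle substrate."""
    grid = make_cubic_grid([0.0, 0.0, 0.0], 16.0, 64)
    deposit_gaussians(grid, [GaussianSpec([0.0, 0.0, 0.0], 1.0, -1.0)])
    return grid
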