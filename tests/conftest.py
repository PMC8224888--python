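import numpy as np
import pytest

from tripletabf import (
    FreeEnergyField,
    ProbabilityField,
    default_grid,
    probability_from_free_energy,
)


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_energy_field(grid, rng):
    """A random fully masked free-energy field on the default 10^3 grid."""
    g = rng.uniform(0.0, 6.0, grid.shape)
    return FreeEnergyField.from_values(grid, g)


@pytest.fixture
def random_probability_field(random_energy_field):
    return probability_from_free_energy(random_energy_field)


def make_probability(grid, rng, sparsity=0.0):
    """Random normalized probability field; optionally unmask a fraction."""
    w = rng.uniform(0.0, 1.0, grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    if sparsity > 0:
        mask = rng.uniform(size=grid.shape) > sparsity
        if not mask.any():
            mask.flat[0] = True
    return ProbabilityField.from_weights(grid, np.where(mask, w, 0.0), mask)
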