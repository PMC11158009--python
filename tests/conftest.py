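import numpy as np
import pytest

from centime import DiscreteEventDistribution, TimeGrid


@pytest.fixture
def uniform4():
    """Uniform pmf on a Tmax=4 grid."""
    return DiscreteEventDistribution.from_pmf(TimeGrid(4), np.full(4, 0.25))


@pytest.fixture
def random_dist():
    """Factory for random normalised distributions on a given grid."""

    def make(t_max: int, seed: int) -> DiscreteEventDistribution:
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(t_max))
        return DiscreteEventDistribution.from_pmf(TimeGrid(t_max), w)

    return make


def point_mass(t_max: int, at: int) -> DiscreteEventDistribution:
    pmf = np.zeros(t_max)
    pmf[at - 1] = 1.0
    return DiscreteEventDistribution.from_pmf(TimeGrid(t_max), pmf)
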