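import numpy as np
import pytest

from drinksim import SimulationConfig, population_mean_parameters


@pytest.fixture
def mean_params():
    """Cohort-mean parameter vector with a mid-range drinker profile."""
    return population_mean_parameters()


@pytest.fixture
def short_config():
    return SimulationConfig(n_days=3, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
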