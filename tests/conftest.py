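import numpy as np
import pytest
from hypothesis import settings

from fcbwas.synthetic import SimulationConfig, region_link_matrix, simulate_cohort

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def effect_cohort():
    """Default study conditions: 3 sites x (40+40), 10 planted hub links."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def effect_links(effect_cohort):
    return region_link_matrix(effect_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Same conditions but no planted effects (covariate effects stay on)."""
    return simulate_cohort(SimulationConfig(seed=11, effect_map=[]))


@pytest.fixture(scope="session")
def null_links(null_cohort):
    return region_link_matrix(null_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
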