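import numpy as np
import pytest

from bhq.simulate import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_per_group=8, grid_shape=(16, 16, 16), n_regions=4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
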