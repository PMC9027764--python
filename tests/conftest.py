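import numpy as np
import pytest

from mmrlink.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def small_config():
    """Desk-scale cohort: the 0.35 s deviant peak sits on the 100 Hz grid."""
    return SimulationConfig(
        n_per_group=5,
        n_labels=20,
        sample_rate=100.0,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
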