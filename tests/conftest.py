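import numpy as np
import pytest

from clutchkit.config import StudyConfig
from clutchkit.simulate import simulate_study


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_study(default_config):
    """One default-sized study (46 nests), shared across tests."""
    return simulate_study(default_config, seed=7)


@pytest.fixture(scope="session")
def big_study():
    """A 300-pair study for moment-recovery checks."""
    return simulate_study(StudyConfig(n_pairs=300, n_control_dropped=0), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220528)
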