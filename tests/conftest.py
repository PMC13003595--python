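import numpy as np
import pytest
from hypothesis import settings

from hibpn.cohort import CohortConfig, generate_cohort
from hibpn.training import TrainConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant cohort under default study conditions."""
    return generate_cohort(CohortConfig(n_participants=300, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 2,000-participant cohort for signal-recovery checks."""
    return generate_cohort(CohortConfig(n_participants=2000, seed=42))


@pytest.fixture()
def fast_train_config():
    return TrainConfig(epochs=300, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
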