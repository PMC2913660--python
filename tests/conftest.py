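import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bchm.datagen import ScenarioConfig, generate_dataset, modelling_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One default four-year LRI scenario, shared across tests."""
    return generate_dataset(ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def default_frame(default_dataset):
    """Tidy daily covariate + count table for the default scenario."""
    return modelling_frame(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
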