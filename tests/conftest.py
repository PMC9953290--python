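import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230208)


@pytest.fixture(scope="session")
def default_config():
    from trophos import default_scenario

    return default_scenario(seed=42)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    from trophos import generate_dataset

    return generate_dataset(default_config)
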