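import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from samarac.synth import example_populations

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def examples():
    return example_populations()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
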