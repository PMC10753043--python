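import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mozsight import EyeParameters, build_eye_array

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return EyeParameters()


@pytest.fixture(scope="session")
def eye37(default_params):
    return build_eye_array(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231127)
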