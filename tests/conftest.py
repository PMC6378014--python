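import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adipoflame import SubjectProfile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def diaz_profile():
    return SubjectProfile(body_weight_0=73.7, height=1.75, age=36, gender="male")


@pytest.fixture
def tremblay_profile():
    return SubjectProfile(body_weight_0=60.3, height=1.72, age=36, gender="male")
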