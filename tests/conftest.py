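import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grcsim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def anatomy():
    return grcsim.AnatomyParams()


@pytest.fixture
def feedback_params():
    return grcsim.GolgiFeedbackParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
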