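import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcdpop as m

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def human():
    return m.HUMAN


@pytest.fixture
def rat():
    return m.RAT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def click_pair():
    """Zero-lag click/flash pair long enough for +/-0.5 s lag sweeps: the
    window holds the stimulus plus the full low-pass response tail."""
    return m.make_click_flash(lag=0.0, duration=3.6, fs=500.0)
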