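import numpy as np
import pytest

from nvc import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A 600-s default-parameter session shared by read-only tests."""
    params = sd.GenParams(seed=7, stim_times=np.arange(20.0, 280.0, 35.0), heart_amp=0.003)
    session, truth = sd.generate_session(params, duration_s=600.0)
    return params, session, truth
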