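import numpy as np
import pytest
from hypothesis import settings

from scrcompare.io import EventTable, ScrRecording
from scrcompare.kernel import make_kernel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def kernel10():
    """Default canonical kernel sampled at the 10 Hz analysis rate."""
    return make_kernel(10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_recording():
    rng = np.random.default_rng(7)
    values = 5.0 + 0.01 * rng.standard_normal(600)
    return ScrRecording(subject_id="s1", fs=10.0, values=values)


@pytest.fixture()
def two_condition_events():
    return EventTable(
        np.array([5.0, 14.0, 23.0, 32.0]),
        np.array(["neutral", "aversive", "neutral", "aversive"], dtype=object),
    )
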