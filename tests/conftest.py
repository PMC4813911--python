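import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qsa import (
    EEGSession,
    Event,
    ProtocolSpec,
    SignalModelParams,
    generate_session,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolSpec:
    """4 cues x (2 s cue + 1 s rest) at 32 Hz: 384 samples, 8 segments."""
    return ProtocolSpec(cue_duration=2.0, rest_duration=1.0, n_cues=4, sample_rate=32.0)


@pytest.fixture(scope="session")
def small_session(small_protocol) -> EEGSession:
    return generate_session(small_protocol, SignalModelParams(seed=7))


@pytest.fixture(scope="session")
def toy_session() -> EEGSession:
    """Three labelled segments of unequal length over 4 random channels."""
    rng = np.random.default_rng(42)
    events = [Event(1, 0, 12), Event(0, 12, 8), Event(2, 20, 10)]
    return EEGSession(
        sample_rate=10.0,
        channel_names=["FC5", "FC6", "P7", "P8"],
        data=rng.normal(size=(30, 4)),
        events=events,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
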