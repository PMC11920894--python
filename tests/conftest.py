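import numpy as np
import pytest

from sonospike import StimulusProtocol, generate_session, preset


@pytest.fixture(scope="session")
def protocol():
    """The standard stimulation protocol: 1.5 MHz carrier, 1500 Hz PRF,
    200 us bursts, 67 ms stimulus, 505 trials every 2.5 s with 10% jitter."""
    return StimulusProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced trial count for fast unit tests."""
    return StimulusProtocol(n_trials=60)


@pytest.fixture(scope="session")
def small_fsu_session(short_protocol):
    """A small awake fast-spiking session reused across tests."""
    return generate_session([(preset("awake_fsu"), 5)], short_protocol, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
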