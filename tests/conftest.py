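import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mealbci import SessionProtocol, SynthesisParams, synth_session  # noqa: E402


@pytest.fixture(scope="session")
def small_session():
    """One-trial session (5 cycles) at high SNR: fast, fully detectable."""
    protocol = SessionProtocol(n_trials=1, cycles_per_trial=5)
    params = SynthesisParams(seed=11, ssvep_snr=4.0)
    rec, truth = synth_session(protocol, params)
    return protocol, params, rec, truth


@pytest.fixture(scope="session")
def full_session():
    """Six-trial, 30-cycle session at high SNR for session-level scoring."""
    protocol = SessionProtocol()
    params = SynthesisParams(seed=7, ssvep_snr=4.0)
    rec, truth = synth_session(protocol, params)
    return protocol, params, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
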