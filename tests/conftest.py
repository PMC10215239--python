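import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crmkit import synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 500.0


@pytest.fixture
def quiet_subject():
    """Noise-free, wander-free subject for analytic comparisons."""
    return synth.SubjectParams(
        "Q0", hdd_step=8, noise_sd=0.0, wander_amp=0.0, seed=7
    )


@pytest.fixture
def noisy_subject():
    return synth.SubjectParams("N0", hdd_step=6, seed=11)


@pytest.fixture
def short_protocol():
    """Default pressure ladder with 20 s steps, for fast sessions."""
    return synth.make_protocol(step_duration=20.0)


@pytest.fixture
def quiet_session(quiet_subject, short_protocol):
    return synth.simulate_session(quiet_subject, short_protocol, fs=FS)


@pytest.fixture
def noisy_session(noisy_subject, short_protocol):
    return synth.simulate_session(noisy_subject, short_protocol, fs=FS)


def analytic_shape(params):
    """Closed-form two-Gaussian beat shape (unscaled), for oracles."""

    def s(t):
        t = np.asarray(t, dtype=float)
        g1 = np.exp(-((t - params["mu1"]) ** 2) / (2 * params["s1"] ** 2))
        g2 = np.exp(-((t - params["mu2"]) ** 2) / (2 * params["s2"] ** 2))
        return g1 + params["a2"] * g2

    return s
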