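import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A 10-minute 30 Hz paretic-arm session with moderate functional use."""
    from armuse.synth import MovementProfile, generate_session

    profile = MovementProfile(functional_fraction=0.35)
    trace, truth = generate_session(profile, rate_hz=30, minutes=10, seed=11)
    return trace, truth


@pytest.fixture(scope="session")
def small_windows(small_session):
    """Scaled windows + labels from the small session (separable 2-class)."""
    from armuse.preprocess import RobustWindowScaler, segment_and_window

    trace, truth = small_session
    ds = segment_and_window(trace, truth, subject_id="s0")
    scaler = RobustWindowScaler().fit(ds.windows)
    return scaler.transform(ds.windows), ds.y
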