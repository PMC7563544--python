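import numpy as np
import pytest
from hypothesis import settings

from intentnet.pipeline import analyze_session
from intentnet.synthetic import SessionConfig, generate_session

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """A 30-trial default-condition session, generated once per test run."""
    cfg = SessionConfig(n_trials=30, seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_metrics(small_session):
    """Full analysis of the small session."""
    s = small_session
    return analyze_session(s.kinematics, s.ecg, s.trials, s.config.handedness)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
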