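import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_events():
    """One-session default event schedule shared by read-only tests."""
    from localglobal.paradigm import generate_experiment

    return generate_experiment(n_sessions=1, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """A small default-noise study reused by read-only pipeline tests."""
    from localglobal.synth import simulate_study

    return simulate_study(n_subjects=8, n_sessions=1, seed=42)
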