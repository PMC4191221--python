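import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import meddrive as md

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ladder60() -> md.DurationLadder:
    return md.build_ladder(1000.0 / 60.0)


@pytest.fixture(scope="session")
def default_profile() -> md.ObserverProfile:
    return md.ObserverProfile()


@pytest.fixture(scope="session")
def session_record(default_profile) -> md.SessionRecord:
    """One simulated battery run shared across read-only tests."""
    return md.simulate_session(default_profile, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
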