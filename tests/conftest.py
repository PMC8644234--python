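import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

#: canonical three-phase flash-decay parameters: fast ~475 us (63%),
#: middle ~75 ms (15%), slow hyperbolic ~3.8 s (22%)
CANONICAL_DECAY = {"A0": 0.0, "A1": 0.63, "A2": 0.15, "A3": 0.22,
                   "T1": 4.75e-4, "T2": 7.5e-2, "T3": 3.8}


@pytest.fixture
def canonical_decay():
    return dict(CANONICAL_DECAY)


@pytest.fixture
def ojip_landmarks():
    return {"F0": 0.2, "F300": 0.28, "FJ": 0.5, "FI": 0.8, "FM": 1.0}


@pytest.fixture
def pam_trajectories():
    """Monotone induction: rising NPQ and donor-side limitation, falling YII."""
    return {
        "YII": [(0.0, 0.75), (960.0, 0.45)],
        "NPQ": [(0.0, 0.0), (960.0, 2.0)],
        "YND": [(0.0, 0.0), (960.0, 0.7)],
        "YNA": [(0.0, 0.8), (960.0, 0.05)],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
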