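import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from courtrack.synthetic_arena import (ArenaConfig, BehaviorParams,
                                       NoiseParams, simulate_session)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


ZERO_NOISE = NoiseParams(keypoint_jitter_mm=0.0, dropout_base=0.0,
                         dropout_speed_gain=0.0, sexlabel_error=0.0,
                         occlusion_dist_mm=0.0, conf_low=1.0, conf_high=1.0,
                         seed=0)


@pytest.fixture(scope="session")
def short_arena():
    """A two-female session short enough for per-test tracking runs."""
    return ArenaConfig(duration_s=60.0, fps=30.0, n_females=2)


@pytest.fixture(scope="session")
def short_session(short_arena):
    traj, bouts = simulate_session(short_arena, BehaviorParams(seed=11))
    return traj, bouts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
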