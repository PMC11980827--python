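import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from myodecode import (  # noqa: E402
    CuffModel,
    TrajectoryConfig,
    generate_trajectory,
    synthesize_emg,
    template_for,
)


@pytest.fixture(scope="session")
def short_recording():
    """One 7.5-s grasp recording (one full guide cycle) with fixed seed."""
    cfg = TrajectoryConfig(duration_s=7.5)
    traj = generate_trajectory(template_for("grasp"), cfg)
    windows = synthesize_emg(traj, CuffModel(rng_seed=7))
    return traj, windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
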