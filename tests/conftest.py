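import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mocapskill import HandTrack, KinematicsConfig, MotionRecording, load_score_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(left_pos, right_pos, t=None, fps=25.0, trial_id="test"):
    """Build a validated recording from raw position arrays (orientation 0)."""
    left_pos = np.asarray(left_pos, dtype=float)
    right_pos = np.asarray(right_pos, dtype=float)
    n = len(left_pos)
    if t is None:
        t = np.arange(n) / fps
    zeros_l = np.zeros((n, 3))
    zeros_r = np.zeros((n, 3))
    return MotionRecording(
        trial_id=trial_id,
        left=HandTrack(t=t, pos=left_pos, orient=zeros_l),
        right=HandTrack(t=t, pos=right_pos, orient=zeros_r),
        nominal_fps=fps,
    )


def random_walk_recording(rng, n_frames=60, step_mm=20.0, fps=25.0, offset=(300.0, 0.0, 0.0)):
    """Random-walk pair of hands; the right hand starts at ``offset``."""
    left = np.cumsum(rng.normal(0, step_mm, size=(n_frames, 3)), axis=0)
    right = np.asarray(offset) + np.cumsum(rng.normal(0, step_mm, size=(n_frames, 3)), axis=0)
    return make_recording(left, right, fps=fps)


@pytest.fixture(scope="session")
def study_trials():
    """The packaged 10-participant x 2-cycle score table."""
    return load_score_table()


@pytest.fixture()
def kin_cfg():
    return KinematicsConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
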