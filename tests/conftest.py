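import numpy as np
import pytest

from fapa import synthetic
from fapa.video_io import LandmarkSet


@pytest.fixture(scope="session")
def sham_schedule():
    schedule, labels = synthetic.simulate_timeline("sham")
    return schedule, labels


@pytest.fixture(scope="session")
def short_session(sham_schedule):
    """Baseline session of a sham timeline, 2 s at 10 fps (small, fast)."""
    schedule, _ = sham_schedule
    stack, truth = synthetic.render_face_video(
        schedule, session=0, size=96, fps=10.0, duration_s=2.0, seed=11
    )
    return stack, truth


@pytest.fixture
def square_landmarks():
    """Well-separated reference landmarks inside a 96x96 frame."""
    return LandmarkSet(
        eye_1=(20.0, 30.0),
        eye_2=(25.0, 60.0),
        nose_1=(60.0, 15.0),
        nose_2=(70.0, 40.0),
    )


def landmarks_from_points(points: np.ndarray) -> LandmarkSet:
    return LandmarkSet(
        eye_1=tuple(points[0]),
        eye_2=tuple(points[1]),
        nose_1=tuple(points[2]),
        nose_2=tuple(points[3]),
    )
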