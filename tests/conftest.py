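import numpy as np
import pytest

from orpose.io import COCO_KEYPOINTS, KEYPOINT_INDEX, PoseFrame, ZoneSet
from orpose.simulate import _STANCE_OFFSETS, default_zones
from orpose.tracking import Track


@pytest.fixture
def zones() -> ZoneSet:
    return default_zones()


def make_pose(
    frame: int = 0,
    points: dict[str, tuple[float, float]] | None = None,
    confidence: float = 0.9,
    person_id: int | None = None,
) -> PoseFrame:
    """PoseFrame with only the named keypoints present."""
    kp = np.full((17, 3), np.nan)
    for name, (x, y) in (points or {}).items():
        kp[KEYPOINT_INDEX[name]] = (x, y, confidence)
    return PoseFrame(frame_index=frame, keypoints=kp, person_hypothesis_id=person_id)


def full_pose(frame: int, anchor: tuple[float, float], confidence: float = 0.9) -> PoseFrame:
    """Complete 17-keypoint pose in the standard stance at an anchor."""
    pts = {
        name: (anchor[0] + dx, anchor[1] + dy) for name, (dx, dy) in _STANCE_OFFSETS.items()
    }
    return make_pose(frame, pts, confidence)


def random_track(
    rng: np.random.Generator,
    track_id: int,
    n_frames: int,
    dropout: float = 0.1,
) -> Track:
    """Adversarial random-walk track for oracle-equivalence testing.

    The anchor wanders around and through the table zones with a per-person
    step scale chosen so 5-frame displacements straddle the movement
    threshold; keypoint confidences are uniform on [0, 1] so the presence
    threshold matters, and keypoints drop out at random.
    """
    anchor = rng.uniform((300.0, 200.0), (700.0, 500.0))
    sigma = rng.uniform(0.0, 8.0)
    track = Track(track_id=track_id, state="confirmed")
    for t in range(n_frames):
        anchor = anchor + rng.normal(0.0, sigma, size=2)
        kp = np.empty((17, 3))
        for name, (dx, dy) in _STANCE_OFFSETS.items():
            i = KEYPOINT_INDEX[name]
            kp[i, :2] = (anchor[0] + dx, anchor[1] + dy)
        kp[:, :2] += rng.normal(0.0, 3.0, size=(17, 2))
        kp[:, 2] = rng.uniform(0.0, 1.0, size=17)
        kp[rng.random(17) < dropout] = np.nan
        track.poses[t] = PoseFrame(frame_index=t, keypoints=kp)
    track.last_seen = n_frames - 1
    return track
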