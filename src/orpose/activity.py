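"""Per-frame "active at the operating table" classification.

A staff member is counted as active at the table in a frame when two
conditions hold simultaneously:

1. **Zone condition** — both wrists lie inside the annotated table (wrist)
   area, both shoulders inside the shoulder area, and the head centroid
   (over nose, eyes and ears) inside the head area. Requiring the shoulder
   and head subsets as well as the wrists guards against camera-perspective
   artifacts: a wrist reaching over the table from a passer-by does not
   satisfy the shoulder/head conditions and is not misclassified.

2. **Movement veto** — the displacement of the shoulders and head over a
   5-frame window must not exceed 17.5 pixels; faster movement indicates
   someone walking past the table rather than working at it. Wrist motion is
   deliberately ignored (wrists move during table work) and leg keypoints
   never enter any rule (legs are unreliable under surgical aprons and
   ceiling-camera angles).

Frames where a required keypoint is missing, or where the displacement
window is unavailable (track warm-up or gaps), are *undetermined* rather
than inactive, so detector dropout cannot masquerade as evidence of
inactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import shapely
from pydantic import BaseModel, model_validator

from .io import (
    HEAD_KEYPOINTS,
    KEYPOINT_INDEX,
    SHOULDER_KEYPOINTS,
    WRIST_KEYPOINTS,
    PoseFrame,
    ZoneSet,
)

Status = Literal["active", "inactive", "undetermined"]
ZoneResult = Literal["pass", "fail", "undetermined"]

ACTIVE, INACTIVE, UNDETERMINED = "active", "inactive", "undetermined"


class ActivityParams(BaseModel):
    """Classifier parameters.

    displacement_threshold : px over the window; movement strictly above it
        vetoes activity. Default 17.5 px over 5 frames.
    window : displacement window length in frames.
    min_confidence : a keypoint below this confidence counts as absent.
    aggregator : how left-shoulder/right-shoulder/head displacements are
        combined before the threshold comparison.
    """

    displacement_threshold: float = 17.5
    window: int = 5
    min_confidence: float = 0.3
    aggregator: Literal["mean", "max"] = "mean"

    @model_validator(mode="after")
    def _check(self):
        if self.displacement_threshold <= 0:
            raise ValueError("displacement_threshold must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")
        return self


@dataclass
class ActivitySeries:
    """Per-frame activity labels for one track, plus derived active intervals.

    ``intervals`` are half-open ``[start, end)`` frame ranges that exactly
    cover the frames labelled active. ``zone`` records the zone-test outcome
    per frame; downstream occupancy estimators use it to treat the two
    failure modes (zone undetermined vs displacement unavailable)
    separately, which keeps occupancy unbiased under keypoint dropout.
    """

    track_id: int
    frames: np.ndarray  # sorted frame indices present in the track
    status: np.ndarray  # object array of status strings, parallel to frames
    zone: np.ndarray = None  # object array of zone-test results, parallel to frames
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def status_at(self, frame: int) -> str | None:
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self.frames) and self.frames[idx] == frame:
            return str(self.status[idx])
        return None

    def counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.status, return_counts=True)
        out = {ACTIVE: 0, INACTIVE: 0, UNDETERMINED: 0}
        out.update(dict(zip((str(v) for v in vals), (int(c) for c in counts))))
        return out


def head_point(pose: PoseFrame, min_confidence: float = 0.3) -> Optional[np.ndarray]:
    """Centroid of the present head keypoints (nose, eyes, ears).

    Returns None when no head keypoint reaches ``min_confidence``.
    """
    idx = [KEYPOINT_INDEX[name] for name in HEAD_KEYPOINTS]
    kp = pose.keypoints[idx]
    ok = ~np.isnan(kp).any(axis=1)
    ok &= np.where(ok, kp[:, 2] >= min_confidence, False)
    if not ok.any():
        return None
    return kp[ok, :2].mean(axis=0)


def _zone_contains(zone, point: np.ndarray) -> bool:
    # boundary-inclusive membership keeps edge cases deterministic
    return bool(shapely.intersects_xy(zone, point[0], point[1]))


def zone_test(pose: PoseFrame, zones: ZoneSet, min_confidence: float = 0.3) -> ZoneResult:
    """Three-zone positional test for table work.

    ``pass`` requires both wrists in the wrist zone, both shoulders in the
    shoulder zone and the head centroid in the head zone; ``undetermined``
    if any required point is absent; ``fail`` otherwise.
    """
    required: list[tuple[np.ndarray | None, object]] = []
    for name in WRIST_KEYPOINTS:
        pt = pose.point(name)
        if pt is not None and pose.keypoints[KEYPOINT_INDEX[name], 2] < min_confidence:
            pt = None
        required.append((pt, zones.wrist_zone))
    for name in SHOULDER_KEYPOINTS:
        pt = pose.point(name)
        if pt is not None and pose.keypoints[KEYPOINT_INDEX[name], 2] < min_confidence:
            pt = None
        required.append((pt, zones.shoulder_zone))
    required.append((head_point(pose, min_confidence), zones.head_zone))

    if any(pt is None for pt, _ in required):
        return "undetermined"
    if all(_zone_contains(zone, pt) for pt, zone in required):
        return "pass"
    return "fail"


def _tracked_points(pose: PoseFrame, min_confidence: float) -> Optional[np.ndarray]:
    """Stack (left shoulder, right shoulder, head centroid); None if any absent."""
    pts = []
    for name in SHOULDER_KEYPOINTS:
        row = pose.keypoints[KEYPOINT_INDEX[name]]
        if np.isnan(row).any() or row[2] < min_confidence:
            return None
        pts.append(row[:2])
    head = head_point(pose, min_confidence)
    if head is None:
        return None
    pts.append(head)
    return np.asarray(pts)


def displacement(
    track,
    t: int,
    window: int = 5,
    min_confidence: float = 0.3,
    aggregator: str = "mean",
) -> Optional[float]:
    """Shoulder/head displacement between frames ``t - window`` and ``t``.

    Endpoint-to-endpoint distance (not path length) per point, aggregated
    over {left shoulder, right shoulder, head centroid}. Returns None during
    the warm-up (``t < window``), across track gaps, or when any of the three
    points is absent at either endpoint.
    """
    if t < window:
        return None
    a = track.poses.get(t - window)
    b = track.poses.get(t)
    if a is None or b is None:
        return None
    pa = _tracked_points(a, min_confidence)
    pb = _tracked_points(b, min_confidence)
    if pa is None or pb is None:
        return None
    dists = np.linalg.norm(pb - pa, axis=1)
    return float(dists.max() if aggregator == "max" else dists.mean())


def classify_frame(track, t: int, zones: ZoneSet, params: ActivityParams | None = None) -> Status:
    """Classify one frame of a track.

    Active iff the zone test passes and the shoulder/head displacement does
    not exceed the threshold (strict: displacement exactly at the threshold
    still counts as active). Inactive on a zone fail or on an exceeded
    threshold; undetermined otherwise.
    """
    params = params or ActivityParams()
    pose = track.poses.get(t)
    if pose is None:
        return UNDETERMINED
    zr = zone_test(pose, zones, params.min_confidence)
    if zr == "fail":
        return INACTIVE
    disp = displacement(track, t, params.window, params.min_confidence, params.aggregator)
    if disp is not None and disp > params.displacement_threshold:
        return INACTIVE
    if zr == "undetermined" or disp is None:
        return UNDETERMINED
    return ACTIVE


def _active_intervals(frames: np.ndarray, status: np.ndarray) -> list[tuple[int, int]]:
    intervals: list[tuple[int, int]] = []
    start = None
    prev = None
    for f, s in zip(frames, status):
        if s == ACTIVE:
            if start is None or prev is None or f != prev + 1:
                if start is not None:
                    intervals.append((start, prev + 1))
                start = int(f)
            prev = int(f)
        else:
            if start is not None:
                intervals.append((start, prev + 1))
                start = None
    if start is not None:
        intervals.append((start, prev + 1))
    return intervals


def classify_track(track, zones: ZoneSet, params: ActivityParams | None = None) -> ActivitySeries:
    """Classify every frame of a track and derive active intervals."""
    params = params or ActivityParams()
    if not track.poses:
        raise ValueError("cannot classify an empty track")
    frames = np.array(sorted(track.poses), dtype=int)
    zone = np.array(
        [zone_test(track.poses[int(t)], zones, params.min_confidence) for t in frames],
        dtype=object,
    )
    status = np.empty(len(frames), dtype=object)
    for i, t in enumerate(frames):
        if zone[i] == "fail":
            status[i] = INACTIVE
            continue
        disp = displacement(track, int(t), params.window, params.min_confidence, params.aggregator)
        if disp is not None and disp > params.displacement_threshold:
            status[i] = INACTIVE
        elif zone[i] == "undetermined" or disp is None:
            status[i] = UNDETERMINED
        else:
            status[i] = ACTIVE
    return ActivitySeries(
        track_id=track.track_id,
        frames=frames,
        status=status,
        zone=zone,
        intervals=_active_intervals(frames, status),
    )
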