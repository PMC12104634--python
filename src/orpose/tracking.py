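"""Two-stage pose-detection association into identity-stable tracks.

The association strategy follows the BYTE idea of splitting detections by
confidence: confident detections are matched to tracks first, and the
leftover tracks get a second chance against low-confidence detections,
which recovers partially occluded or blurred staff members instead of
discarding them. It is adapted to pose data by scoring candidate pairs with
a blend of bounding-box overlap (IoU) and an OKS-style keypoint-distance
term, rather than box overlap alone.

No motion model is used: operating-room staff move slowly relative to the
frame rate, so the last observed pose represents a track. Assignment within
each stage is solved optimally (Hungarian algorithm via
``scipy.optimize.linear_sum_assignment``), maximizing total similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.optimize import linear_sum_assignment

from .io import PoseFrame


class TrackerParams(BaseModel):
    """Association parameters; defaults follow common practice for
    confidence-split tracking and are all configuration-exposed."""

    high_conf_threshold: float = 0.5
    low_conf_threshold: float = 0.1
    match_threshold: float = 0.3
    max_age: int = 30
    min_hits: int = 3
    iou_weight: float = 0.5  # blend weight between box IoU and the keypoint term
    bbox_margin: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.low_conf_threshold < self.high_conf_threshold <= 1.0:
            raise ValueError("need 0 <= low_conf_threshold < high_conf_threshold <= 1")
        if not 0.0 <= self.match_threshold <= 1.0:
            raise ValueError("match_threshold must be in [0, 1]")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if not 0.0 <= self.iou_weight <= 1.0:
            raise ValueError("iou_weight must be in [0, 1]")
        return self


@dataclass
class Track:
    """An identity-resolved pose time series (gaps allowed)."""

    track_id: int
    poses: dict[int, PoseFrame] = field(default_factory=dict)
    state: Literal["tentative", "confirmed", "lost"] = "tentative"
    last_seen: int = -1

    def add(self, frame: int, pose: PoseFrame, min_hits: int) -> None:
        if frame in self.poses:
            raise ValueError(f"track {self.track_id} already has a pose at frame {frame}")
        if self.poses and frame <= max(self.poses):
            raise ValueError("poses must be added in increasing frame order")
        self.poses[frame] = pose
        self.last_seen = frame
        if self.state == "tentative" and len(self.poses) >= min_hits:
            self.state = "confirmed"

    @property
    def last_pose(self) -> PoseFrame:
        return self.poses[max(self.poses)]

    def __len__(self) -> int:
        return len(self.poses)


def pose_bbox(pose: PoseFrame, margin: float = 0.0) -> Optional[np.ndarray]:
    """Tight axis-aligned box (x0, y0, x1, y1) over present keypoints,
    expanded on every side by ``margin`` times the corresponding extent.

    Returns None when fewer than 2 keypoints are present (such a pose is
    unusable for overlap-based matching).
    """
    mask = pose.present_mask()
    if mask.sum() < 2:
        return None
    xy = pose.keypoints[mask, :2]
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    dx = (x1 - x0) * margin
    dy = (y1 - y0) * margin
    return np.array([x0 - dx, y0 - dy, x1 + dx, y1 + dy])


def _box_iou(a: np.ndarray, b: np.ndarray) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return float(inter / (area_a + area_b - inter))


def pose_similarity(a: PoseFrame, b: PoseFrame, params: TrackerParams | None = None) -> float:
    """Similarity in [0, 1] between two poses.

    A convex blend ``w * IoU + (1 - w) * exp(-msd / (2 s^2))`` of box
    overlap and an OKS-style term, where ``msd`` is the mean squared
    distance over keypoints present in both poses and ``s`` is the mean
    bounding-box diagonal of the two poses. Symmetric; 1 for identical
    poses; with ``iou_weight = 1`` reduces to plain box IoU.
    """
    params = params or TrackerParams()
    box_a = pose_bbox(a, params.bbox_margin)
    box_b = pose_bbox(b, params.bbox_margin)
    shared = a.present_mask() & b.present_mask()
    if box_a is None or box_b is None:
        return 0.0
    iou = _box_iou(box_a, box_b)
    if params.iou_weight == 1.0:
        return iou
    if not shared.any():
        kp_term = 0.0
    else:
        d2 = np.sum((a.keypoints[shared, :2] - b.keypoints[shared, :2]) ** 2, axis=1)
        diag_a = float(np.hypot(box_a[2] - box_a[0], box_a[3] - box_a[1]))
        diag_b = float(np.hypot(box_b[2] - box_b[0], box_b[3] - box_b[1]))
        s = 0.5 * (diag_a + diag_b)
        if s == 0.0:
            kp_term = 1.0 if float(d2.mean()) == 0.0 else 0.0
        else:
            kp_term = float(np.exp(-d2.mean() / (2.0 * s * s)))
    return params.iou_weight * iou + (1.0 - params.iou_weight) * kp_term


@dataclass
class AssociationResult:
    """Outcome of associating one frame's detections with the active tracks."""

    matches: list[tuple[int, int]]  # (track_id, detection index)
    births: list[int]  # detection indices spawning new tracks
    unmatched_tracks: list[int]  # track_ids that received no detection
    unmatched_detections: list[int]  # detections left entirely unassigned


def _match_stage(
    tracks: Sequence[Track],
    detections: Sequence[PoseFrame],
    det_indices: Sequence[int],
    params: TrackerParams,
) -> tuple[list[tuple[int, int]], set[int], set[int]]:
    """Optimal one-to-one matching of tracks to a subset of detections."""
    if not tracks or not det_indices:
        return [], {t.track_id for t in tracks}, set(det_indices)
    sim = np.zeros((len(tracks), len(det_indices)))
    for i, tr in enumerate(tracks):
        for j, di in enumerate(det_indices):
            sim[i, j] = pose_similarity(tr.last_pose, detections[di], params)
    rows, cols = linear_sum_assignment(sim, maximize=True)
    matches = []
    used_t: set[int] = set()
    used_d: set[int] = set()
    for i, j in zip(rows, cols):
        if sim[i, j] >= params.match_threshold:
            matches.append((tracks[i].track_id, det_indices[j]))
            used_t.add(tracks[i].track_id)
            used_d.add(det_indices[j])
    matches.sort()
    leftover_t = {t.track_id for t in tracks} - used_t
    leftover_d = set(det_indices) - used_d
    return matches, leftover_t, leftover_d


def associate(
    tracks: Sequence[Track],
    detections: Sequence[PoseFrame],
    params: TrackerParams | None = None,
) -> AssociationResult:
    """Two-stage association of one frame's detections to active tracks.

    Stage 1 matches all active (tentative or confirmed) tracks to
    high-confidence detections; stage 2 matches the remaining tracks to
    low-confidence detections. Unmatched high-confidence detections become
    births; low-confidence leftovers are dropped.
    """
    params = params or TrackerParams()
    active = [t for t in tracks if t.state != "lost"]
    high = [i for i, d in enumerate(detections) if d.confidence >= params.high_conf_threshold]
    low = [
        i
        for i, d in enumerate(detections)
        if params.low_conf_threshold <= d.confidence < params.high_conf_threshold
    ]

    matches1, leftover_tids, leftover_high = _match_stage(active, detections, high, params)
    remaining = [t for t in active if t.track_id in leftover_tids]
    matches2, leftover_tids2, leftover_low = _match_stage(remaining, detections, low, params)

    return AssociationResult(
        matches=sorted(matches1 + matches2),
        births=sorted(leftover_high),
        unmatched_tracks=sorted(leftover_tids2),
        unmatched_detections=sorted(leftover_high | leftover_low),
    )


def build_tracks(
    detection_stream: Iterable[PoseFrame],
    params: TrackerParams | None = None,
) -> list[Track]:
    """Run the tracker over an ordered detection stream.

    Detections must arrive in non-decreasing frame order (an out-of-order
    frame raises ``ValueError``). Deterministic given the input; every
    detection joins at most one track. Returns all tracks, including lost
    and tentative ones, sorted by track id.
    """
    params = params or TrackerParams()
    by_frame: dict[int, list[PoseFrame]] = {}
    last_frame = None
    for det in detection_stream:
        if last_frame is not None and det.frame_index < last_frame:
            raise ValueError(
                f"detection stream out of order: frame {det.frame_index} after {last_frame}"
            )
        last_frame = det.frame_index
        by_frame.setdefault(det.frame_index, []).append(det)

    tracks: list[Track] = []
    next_id = 0
    for frame in sorted(by_frame):
        detections = by_frame[frame]
        result = associate(tracks, detections, params)
        by_id = {t.track_id: t for t in tracks}
        for tid, di in result.matches:
            by_id[tid].add(frame, detections[di], params.min_hits)
        for di in result.births:
            tr = Track(track_id=next_id)
            next_id += 1
            tr.add(frame, detections[di], params.min_hits)
            tracks.append(tr)
        for tr in tracks:
            if tr.state != "lost" and frame - tr.last_seen > params.max_age:
                tr.state = "lost"
    return sorted(tracks, key=lambda t: t.track_id)
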