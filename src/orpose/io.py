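"""Readers, writers and validated domain types for pose analytics data.

All tabular formats are UTF-8 CSV with '.' decimal separators; geometric and
timeline annotations are JSON. Coordinates are image pixels with the origin
at the top-left corner and y increasing downward; frame indices are 0-based.
Missing keypoints are encoded as empty fields, which is distinct from a
keypoint observed with confidence 0.

Readers validate on load and reject invariant-violating input rather than
coercing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

#: COCO-17 keypoint vocabulary, in canonical order.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

HEAD_KEYPOINTS: tuple[str, ...] = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")
SHOULDER_KEYPOINTS: tuple[str, ...] = ("left_shoulder", "right_shoulder")
WRIST_KEYPOINTS: tuple[str, ...] = ("left_wrist", "right_wrist")

SURGERY_TYPES: tuple[str, ...] = ("OS", "MIS", "RAS")
PHASES: tuple[int, ...] = (1, 2, 3)

#: Seven instrument domains: the six original workload domains plus the
#: added job-satisfaction domain.
SURGTLX_DOMAINS: tuple[str, ...] = (
    "mental",
    "physical",
    "temporal",
    "complexity",
    "stress",
    "distractions",
    "satisfaction",
)
ORIGINAL_DOMAINS: tuple[str, ...] = SURGTLX_DOMAINS[:6]

SCALE_MAX: float = 20.0


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


@dataclass
class PoseFrame:
    """One person's keypoint observations in one video frame.

    ``keypoints`` is a (17, 3) float array of (x, y, confidence) rows in
    COCO order; a missing keypoint is a row of NaNs.
    """

    frame_index: int
    keypoints: np.ndarray
    person_hypothesis_id: int | None = None

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (17, 3):
            raise ValueError(f"keypoints must have shape (17, 3), got {kp.shape}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        present = ~np.isnan(kp).any(axis=1)
        if present.any():
            if not np.isfinite(kp[present, :2]).all():
                raise ValueError("present keypoint coordinates must be finite")
            conf = kp[present, 2]
            if ((conf < 0) | (conf > 1)).any():
                raise ValueError("keypoint confidence must lie in [0, 1]")
        self.keypoints = kp

    def present_mask(self, min_confidence: float = 0.0) -> np.ndarray:
        """Boolean mask of keypoints observed with confidence >= threshold."""
        kp = self.keypoints
        ok = ~np.isnan(kp).any(axis=1)
        return ok & (kp[:, 2] >= min_confidence)

    def point(self, name: str) -> np.ndarray | None:
        """(x, y) of a named keypoint, or None if missing."""
        row = self.keypoints[KEYPOINT_INDEX[name]]
        if np.isnan(row).any():
            return None
        return row[:2].copy()

    @property
    def confidence(self) -> float:
        """Detection confidence: mean confidence over present keypoints (0 if none)."""
        mask = self.present_mask()
        if not mask.any():
            return 0.0
        return float(self.keypoints[mask, 2].mean())


def _validated_polygon(coords: Sequence[Sequence[float]], name: str) -> Polygon:
    if len(coords) < 3:
        raise FormatError(f"{name}: polygon needs at least 3 vertices, got {len(coords)}")
    poly = Polygon(coords)
    if not poly.is_valid:
        raise FormatError(f"{name}: polygon is self-intersecting or otherwise invalid")
    if poly.area <= 0:
        raise FormatError(f"{name}: polygon has non-positive area")
    return poly


@dataclass
class ZoneSet:
    """The three annotated operating-table areas for one camera view.

    A staff member counts as posed for table work when both wrists fall in
    ``wrist_zone``, both shoulders in ``shoulder_zone`` and the head centroid
    in ``head_zone``. Zone membership is boundary-inclusive.
    """

    wrist_zone: Polygon
    shoulder_zone: Polygon
    head_zone: Polygon
    camera_id: str = "cam0"

    def __post_init__(self) -> None:
        for attr in ("wrist_zone", "shoulder_zone", "head_zone"):
            poly = getattr(self, attr)
            if not isinstance(poly, Polygon):
                poly = _validated_polygon(list(poly), attr)
            else:
                _validated_polygon(list(poly.exterior.coords)[:-1], attr)
            setattr(self, attr, poly)

    def scaled(self, factor: float) -> "ZoneSet":
        """Uniformly rescale all zone polygons about the origin."""
        import shapely.affinity as aff

        return ZoneSet(
            wrist_zone=aff.scale(self.wrist_zone, factor, factor, origin=(0, 0)),
            shoulder_zone=aff.scale(self.shoulder_zone, factor, factor, origin=(0, 0)),
            head_zone=aff.scale(self.head_zone, factor, factor, origin=(0, 0)),
            camera_id=self.camera_id,
        )


@dataclass
class PhaseTimeline:
    """Clinical phase boundaries for one procedure, in frame indices.

    Phase 1 runs from patient entry to first incision, phase 2 from incision
    to closing, phase 3 from closing to patient exit.
    """

    procedure_id: str
    surgery_type: str
    phase1_start: int
    incision: int
    closing: int
    patient_exit: int

    def __post_init__(self) -> None:
        if self.surgery_type not in SURGERY_TYPES:
            raise FormatError(f"unknown surgery_type {self.surgery_type!r}")
        b = (self.phase1_start, self.incision, self.closing, self.patient_exit)
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise FormatError(f"phase boundaries must be strictly increasing, got {b}")

    def phase_bounds(self, phase: int) -> tuple[int, int]:
        """Half-open frame range [start, end) of a phase."""
        edges = (self.phase1_start, self.incision, self.closing, self.patient_exit)
        if phase not in PHASES:
            raise ValueError(f"phase must be in {PHASES}")
        return edges[phase - 1], edges[phase]

    def phase_of(self, frame: int) -> int | None:
        for p in PHASES:
            lo, hi = self.phase_bounds(p)
            if lo <= frame < hi:
                return p
        return None


# ---------------------------------------------------------------------------
# Detections / tracks tables
# ---------------------------------------------------------------------------

_KP_COLUMNS = [f"{name}_{axis}" for name in COCO_KEYPOINTS for axis in ("x", "y", "c")]
DETECTION_COLUMNS = ["frame", "person_id"] + _KP_COLUMNS
TRACK_COLUMNS = ["track_id", "frame"] + _KP_COLUMNS


def _frames_to_table(frames: Iterable[PoseFrame]) -> pd.DataFrame:
    rows = []
    for pf in frames:
        row: dict[str, object] = {
            "frame": pf.frame_index,
            "person_id": pf.person_hypothesis_id,
        }
        for i, name in enumerate(COCO_KEYPOINTS):
            x, y, c = pf.keypoints[i]
            row[f"{name}_x"] = x
            row[f"{name}_y"] = y
            row[f"{name}_c"] = c
        rows.append(row)
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections(frames: Iterable[PoseFrame], path: str | Path) -> None:
    """Write pose detections as a flat CSV, one row per person per frame."""
    _frames_to_table(frames).to_csv(path, index=False)


def _row_to_keypoints(row: pd.Series, path: Path, line: int) -> np.ndarray:
    kp = np.full((17, 3), np.nan)
    for i, name in enumerate(COCO_KEYPOINTS):
        vals = [row.get(f"{name}_{axis}") for axis in ("x", "y", "c")]
        missing = [v is None or (isinstance(v, float) and np.isnan(v)) for v in vals]
        if all(missing):
            continue
        if any(missing):
            raise FormatError(
                f"{path}, line {line}: keypoint {name!r} has partial x/y/c values"
            )
        x, y, c = (float(v) for v in vals)
        if not (np.isfinite(x) and np.isfinite(y)):
            raise FormatError(f"{path}, line {line}: non-finite coordinate for {name!r}")
        if not 0.0 <= c <= 1.0:
            raise FormatError(
                f"{path}, line {line}: field {name}_c = {c} outside [0, 1]"
            )
        kp[i] = (x, y, c)
    return kp


def read_detections(path: str | Path) -> list[PoseFrame]:
    """Read pose detections written by :func:`write_detections`.

    Returns frames sorted by frame index (ties by row order). Malformed rows
    raise :class:`FormatError` naming the line and field.
    """
    path = Path(path)
    df = pd.read_csv(path)
    unknown = [
        c
        for c in df.columns
        if c not in DETECTION_COLUMNS
    ]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown} (unknown keypoint name?)")
    missing_cols = [c for c in ("frame",) if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    frames: list[PoseFrame] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        frame = row["frame"]
        if pd.isna(frame) or int(frame) != frame or frame < 0:
            raise FormatError(f"{path}, line {line}: field 'frame' must be an integer >= 0")
        pid = row.get("person_id")
        pid = None if pd.isna(pid) else int(pid)
        try:
            pf = PoseFrame(
                frame_index=int(frame),
                keypoints=_row_to_keypoints(row, path, line),
                person_hypothesis_id=pid,
            )
        except ValueError as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
        frames.append(pf)
    frames.sort(key=lambda pf: pf.frame_index)
    return frames


def write_tracks(tracks, path: str | Path) -> None:
    """Write tracks as CSV with (track_id, frame) keys; see tracking module."""
    rows = []
    for tr in tracks:
        for frame, pf in sorted(tr.poses.items()):
            row: dict[str, object] = {"track_id": tr.track_id, "frame": frame}
            for i, name in enumerate(COCO_KEYPOINTS):
                x, y, c = pf.keypoints[i]
                row[f"{name}_x"] = x
                row[f"{name}_y"] = y
                row[f"{name}_c"] = c
            rows.append(row)
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path: str | Path):
    """Read a tracks CSV back into Track objects (state is not persisted)."""
    from .tracking import Track  # deferred to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path)
    tracks: dict[int, Track] = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2
        tid = int(row["track_id"])
        frame = int(row["frame"])
        pf = PoseFrame(frame_index=frame, keypoints=_row_to_keypoints(row, path, line))
        tr = tracks.setdefault(tid, Track(track_id=tid))
        if frame in tr.poses:
            raise FormatError(f"{path}, line {line}: duplicate frame {frame} in track {tid}")
        tr.poses[frame] = pf
        tr.last_seen = max(tr.last_seen, frame)
    for tr in tracks.values():
        tr.state = "confirmed"
    return [tracks[t] for t in sorted(tracks)]


# ---------------------------------------------------------------------------
# Zones / timelines (JSON)
# ---------------------------------------------------------------------------


def write_zones(zones: ZoneSet, path: str | Path) -> None:
    payload = {
        "camera_id": zones.camera_id,
        "wrist_zone": [list(p) for p in zones.wrist_zone.exterior.coords[:-1]],
        "shoulder_zone": [list(p) for p in zones.shoulder_zone.exterior.coords[:-1]],
        "head_zone": [list(p) for p in zones.head_zone.exterior.coords[:-1]],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_zones(path: str | Path) -> ZoneSet:
    path = Path(path)
    data = json.loads(path.read_text())
    try:
        return ZoneSet(
            wrist_zone=_validated_polygon(data["wrist_zone"], "wrist_zone"),
            shoulder_zone=_validated_polygon(data["shoulder_zone"], "shoulder_zone"),
            head_zone=_validated_polygon(data["head_zone"], "head_zone"),
            camera_id=str(data.get("camera_id", "cam0")),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing zone {exc}") from exc


def write_timeline(timeline: PhaseTimeline, path: str | Path) -> None:
    payload = {
        "procedure_id": timeline.procedure_id,
        "surgery_type": timeline.surgery_type,
        "boundaries": {
            "phase1_start": timeline.phase1_start,
            "incision": timeline.incision,
            "closing": timeline.closing,
            "patient_exit": timeline.patient_exit,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_timeline(path: str | Path) -> PhaseTimeline:
    path = Path(path)
    data = json.loads(path.read_text())
    try:
        b = data["boundaries"]
        return PhaseTimeline(
            procedure_id=str(data["procedure_id"]),
            surgery_type=str(data["surgery_type"]),
            phase1_start=int(b["phase1_start"]),
            incision=int(b["incision"]),
            closing=int(b["closing"]),
            patient_exit=int(b["patient_exit"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# Schedule records
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "procedure_id",
    "surgery_type",
    "planned_phase1",
    "planned_phase2",
    "planned_phase3",
    "actual_phase1",
    "actual_phase2",
    "actual_phase3",
    "risk_class",
    "emergency",
    "staff_count",
]


def read_schedule(path: str | Path) -> pd.DataFrame:
    """Read hospital schedule records (one row per procedure; minutes).

    Durations may be missing (complete-case filtering happens downstream);
    present durations must be >= 0 and staff counts >= 0.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_type = ~df["surgery_type"].isin(SURGERY_TYPES)
    if bad_type.any():
        line = int(df.index[bad_type][0]) + 2
        raise FormatError(f"{path}, line {line}: field 'surgery_type' not one of {SURGERY_TYPES}")
    dur_cols = [c for c in SCHEDULE_COLUMNS if c.startswith(("planned_", "actual_"))]
    for col in dur_cols:
        neg = df[col].dropna() < 0
        if neg.any():
            line = int(neg[neg].index[0]) + 2
            raise FormatError(f"{path}, line {line}: field {col!r} must be >= 0")
    if (df["staff_count"].dropna() < 0).any():
        raise FormatError(f"{path}: field 'staff_count' must be >= 0")
    return df


def write_schedule(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=SCHEDULE_COLUMNS)


# ---------------------------------------------------------------------------
# Questionnaire tables
# ---------------------------------------------------------------------------

SURGTLX_COLUMNS = ["respondent_id", "domain", "surgery_type", "phase", "score"]


def read_surgtlx(path: str | Path) -> pd.DataFrame:
    """Read questionnaire responses in long format.

    One row per (respondent, domain, surgery type, phase) cell; a missing
    score is an empty field. Scores outside the instrument's [0, 20] scale
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SURGTLX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = ~df["domain"].isin(SURGTLX_DOMAINS)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}, line {line}: field 'domain' not one of {SURGTLX_DOMAINS}")
    bad = ~df["surgery_type"].isin(SURGERY_TYPES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}, line {line}: field 'surgery_type' not one of {SURGERY_TYPES}")
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}, line {line}: field 'phase' not one of {PHASES}")
    scores = df["score"].dropna()
    out = (scores < 0) | (scores > SCALE_MAX)
    if out.any():
        line = int(out[out].index[0]) + 2
        raise FormatError(
            f"{path}, line {line}: field 'score' = {scores[out].iloc[0]} outside [0, {SCALE_MAX:g}]"
        )
    dup = df.duplicated(subset=["respondent_id", "domain", "surgery_type", "phase"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise FormatError(f"{path}, line {line}: duplicate response cell")
    return df


def write_surgtlx(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=SURGTLX_COLUMNS)
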