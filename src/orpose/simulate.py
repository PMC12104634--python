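"""Synthetic operating-room data with known ground truth.

Three generators mirror the three data streams of an OR workflow study:

* :func:`simulate_scene` — ceiling-camera keypoint detections of staff
  around an operating table, with a scheduled ground-truth activity
  pattern, detector-like keypoint jitter and dropout;
* :func:`simulate_surgtlx` — workload/job-satisfaction questionnaire
  responses (7 domains x 3 surgery types x 3 phases on a 0-20 scale);
* :func:`simulate_schedule` — hospital schedule records with planned and
  actual phase durations, patient risk class and staffing.

Scene motion model
------------------
Each staff member owns a station along the table. During a scheduled active
bout they hold a stable working stance with wrists/shoulders/head inside
the three annotated zones. Exactly at bout boundaries they take a single
15 px step between that stance and a "ready" stance whose required
keypoints sit just outside every zone — the step is below the 17.5 px
movement threshold, so the frame at which the zone test flips is exactly
the bout boundary and noiseless classification is frame-exact. Outside
bouts staff idle at the ready stance, optionally walking to a rest position
during long gaps at a speed whose 5-frame displacement exceeds the
threshold by a configurable margin. Staff with no scheduled bouts act as
passers-by, repeatedly walking through the table area fast enough to be
vetoed.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .io import (
    COCO_KEYPOINTS,
    KEYPOINT_INDEX,
    ORIGINAL_DOMAINS,
    PHASES,
    SCALE_MAX,
    SURGERY_TYPES,
    SURGTLX_DOMAINS,
    PhaseTimeline,
    PoseFrame,
    ZoneSet,
)
from .tracking import Track

# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------

#: Movement threshold the scene generator designs its motion around (px per
#: 5-frame window); matches the classifier default.
DISPLACEMENT_THRESHOLD = 17.5
WINDOW = 5
#: Single step between ready and working stance, px (below the threshold).
STANCE_STEP = 15.0


def default_zones(camera_id: str = "cam0") -> ZoneSet:
    """Three nested rectangular areas around the table, innermost for wrists."""
    return ZoneSet(
        wrist_zone=[(400, 300), (600, 300), (600, 420), (400, 420)],
        shoulder_zone=[(380, 280), (620, 280), (620, 440), (380, 440)],
        head_zone=[(360, 260), (640, 260), (640, 460), (360, 460)],
        camera_id=camera_id,
    )


# Stance offsets from the head anchor (x, y): a person working at the table
# from the low-y side, seen from the ceiling.
_STANCE_OFFSETS: dict[str, tuple[float, float]] = {
    "nose": (0.0, 1.0),
    "left_eye": (4.0, -1.0),
    "right_eye": (-4.0, -1.0),
    "left_ear": (8.0, 1.0),
    "right_ear": (-8.0, 1.0),
    "left_shoulder": (15.0, 21.0),
    "right_shoulder": (-15.0, 21.0),
    "left_elbow": (12.0, 31.0),
    "right_elbow": (-12.0, 31.0),
    "left_wrist": (8.0, 41.0),
    "right_wrist": (-8.0, 41.0),
    "left_hip": (10.0, 50.0),
    "right_hip": (-10.0, 50.0),
    "left_knee": (10.0, 62.0),
    "right_knee": (-10.0, 62.0),
    "left_ankle": (10.0, 72.0),
    "right_ankle": (-10.0, 72.0),
}
# With the default zones, anchoring the head at y = 271 puts the wrists at
# y = 312 (12 px inside the wrist zone), shoulders at 292 (12 px inside) and
# the head centroid at ~271.4 (11 px inside); the 15 px ready step moves all
# required points 3-4 px outside their zones.
_TABLE_ANCHOR_Y = 271.0
_REST_Y = 80.0
_CROSS_Y = _TABLE_ANCHOR_Y
_CROSS_X = (290.0, 710.0)


def _stance(anchor_x: float, anchor_y: float) -> np.ndarray:
    kp = np.empty((17, 3))
    for name, (dx, dy) in _STANCE_OFFSETS.items():
        i = KEYPOINT_INDEX[name]
        kp[i, 0] = anchor_x + dx
        kp[i, 1] = anchor_y + dy
        kp[i, 2] = 1.0
    return kp


class SceneConfig(BaseModel):
    """Configuration of one synthetic procedure scene.

    ``activity_schedule`` holds, per staff member, the scheduled active
    bouts as ``(phase, start_fraction, end_fraction)`` within that phase.
    A member with an empty bout list becomes a passer-by who repeatedly
    crosses the table area. ``phase_durations`` are in seconds.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_staff: int
    fps: float = 25.0
    phase_durations: tuple[float, float, float] = (60.0, 180.0, 60.0)
    zone_set: Optional[ZoneSet] = None
    activity_schedule: list[list[tuple[int, float, float]]] = []
    jitter_sd: float = 0.0
    dropout_rate: float = 0.0
    low_conf_rate: float = 0.0
    walk_speed_margin: float = 1.5
    surgery_type: str = "MIS"
    procedure_id: str = "sim-000"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_staff < 0:
            raise ValueError("n_staff must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase_durations must all be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.activity_schedule and len(self.activity_schedule) != self.n_staff:
            raise ValueError("activity_schedule must have one entry per staff member")
        for bouts in self.activity_schedule:
            for phase, a, b in bouts:
                if phase not in PHASES:
                    raise ValueError(f"bout phase {phase} not in {PHASES}")
                if not 0.0 <= a < b <= 1.0:
                    raise ValueError(f"bout fractions must satisfy 0 <= start < end <= 1, got ({a}, {b})")
        if self.walk_speed_margin <= 1.0:
            raise ValueError("walk_speed_margin must exceed 1 (walking must beat the threshold)")
        return self

    @property
    def phase_frames(self) -> tuple[int, int, int]:
        return tuple(int(round(d * self.fps)) for d in self.phase_durations)  # type: ignore

    @property
    def total_frames(self) -> int:
        return sum(self.phase_frames)

    def timeline(self) -> PhaseTimeline:
        f1, f2, f3 = self.phase_frames
        return PhaseTimeline(
            procedure_id=self.procedure_id,
            surgery_type=self.surgery_type,
            phase1_start=0,
            incision=f1,
            closing=f1 + f2,
            patient_exit=f1 + f2 + f3,
        )


@dataclass
class GroundTruth:
    """Noiseless trajectories and scheduled activity for a simulated scene."""

    true_tracks: list[Track]
    true_activity: list[np.ndarray]  # per person, bool per frame
    phase_timeline: PhaseTimeline

    def scheduled_occupancy(self, phase: int) -> float:
        """Combined scheduled active person-time in a phase, as a fraction
        of the phase duration (may exceed 1 with several staff)."""
        lo, hi = self.phase_timeline.phase_bounds(phase)
        if hi == lo:
            return 0.0
        total = sum(int(act[lo:hi].sum()) for act in self.true_activity)
        return total / (hi - lo)


def _bout_frames(config: SceneConfig, bouts: Sequence[tuple[int, float, float]]) -> list[tuple[int, int]]:
    """Absolute half-open frame ranges of a person's scheduled bouts."""
    timeline = config.timeline()
    out = []
    for phase, a, b in bouts:
        lo, hi = timeline.phase_bounds(phase)
        n = hi - lo
        start = lo + int(round(a * n))
        end = lo + int(round(b * n))
        if end > start:
            out.append((start, end))
    out.sort()
    for (s0, e0), (s1, e1) in zip(out, out[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping bouts for one person: {(s0, e0)} and {(s1, e1)}")
    return out


def _worker_anchor_path(
    config: SceneConfig, station_x: float, bouts: list[tuple[int, int]], rng: np.random.Generator
) -> np.ndarray:
    """Head-anchor positions per frame for a staff member with bouts.

    At the table during bouts; at the ready stance (one 15 px step away)
    otherwise; long gaps include a walk to the rest position and back,
    timed to be back at ready at least a full displacement window before
    the next bout.
    """
    n = config.total_frames
    table = np.array([station_x, _TABLE_ANCHOR_Y])
    ready = table + np.array([0.0, -STANCE_STEP])
    rest = np.array([station_x, _REST_Y])
    speed = (DISPLACEMENT_THRESHOLD / WINDOW) * config.walk_speed_margin
    walk_frames = int(math.ceil(np.linalg.norm(rest - ready) / speed))

    anchors = np.tile(ready, (n, 1))
    for start, end in bouts:
        anchors[start:end] = table

    # walk excursions in gaps long enough to go out, pause, and come back
    gaps = []
    prev_end = 0
    for start, end in bouts:
        gaps.append((prev_end, start))
        prev_end = end
    gaps.append((prev_end, n))
    buffer = WINDOW + 1
    for gap_start, gap_end in gaps:
        if gap_end - gap_start < 2 * walk_frames + 3 * buffer:
            continue
        out_start = gap_start + buffer
        back_end = gap_end - buffer
        pause = back_end - out_start - 2 * walk_frames
        for k in range(walk_frames):
            frac = (k + 1) / walk_frames
            anchors[out_start + k] = ready + frac * (rest - ready)
        anchors[out_start + walk_frames : out_start + walk_frames + pause] = rest
        for k in range(walk_frames):
            frac = (k + 1) / walk_frames
            anchors[out_start + walk_frames + pause + k] = rest + frac * (ready - rest)
    return anchors


def _crosser_anchor_path(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Anchor path for a passer-by sweeping across the table area."""
    n = config.total_frames
    speed = (DISPLACEMENT_THRESHOLD / WINDOW) * config.walk_speed_margin
    x0, x1 = _CROSS_X
    cross_frames = int(math.ceil((x1 - x0) / speed))
    pause = int(rng.integers(30, 80))
    anchors = np.empty((n, 2))
    anchors[:, 1] = _CROSS_Y
    t = 0
    x, direction = x0, 1.0
    start_pause = int(rng.integers(0, 40))
    while t < n:
        hold = start_pause if t == 0 else pause
        stop = min(n, t + hold)
        anchors[t:stop, 0] = x
        t = stop
        if t >= n:
            break
        for k in range(cross_frames):
            if t >= n:
                break
            frac = (k + 1) / cross_frames
            anchors[t, 0] = x + direction * frac * (x1 - x0)
            t += 1
        x = x1 if direction > 0 else x0
        direction = -direction
    return anchors


def simulate_scene(config: SceneConfig) -> tuple[list[PoseFrame], GroundTruth]:
    """Generate per-frame keypoint detections plus ground truth.

    Returns detections sorted by frame (with ``person_hypothesis_id`` set to
    the true person index, for evaluation convenience — the tracker ignores
    it) and the :class:`GroundTruth`. Deterministic given ``config.seed``.
    """
    zones = config.zone_set or default_zones()
    # ZoneSet validates its polygons on construction; re-validate here in
    # case a mutated object is passed in.
    ZoneSet(zones.wrist_zone, zones.shoulder_zone, zones.head_zone, zones.camera_id)

    rng = np.random.default_rng(config.seed)
    n_frames = config.total_frames
    timeline = config.timeline()

    if config.n_staff == 0:
        return [], GroundTruth([], [], timeline)

    schedule = config.activity_schedule or [[] for _ in range(config.n_staff)]
    stations = np.linspace(430.0, 570.0, config.n_staff) if config.n_staff > 1 else np.array([500.0])

    true_tracks: list[Track] = []
    true_activity: list[np.ndarray] = []
    anchor_paths: list[np.ndarray] = []
    for person, bouts in enumerate(schedule):
        frames_active = np.zeros(n_frames, dtype=bool)
        if bouts:
            abs_bouts = _bout_frames(config, bouts)
            for s, e in abs_bouts:
                frames_active[s:e] = True
            anchors = _worker_anchor_path(config, float(stations[person]), abs_bouts, rng)
        else:
            anchors = _crosser_anchor_path(config, rng)
        anchor_paths.append(anchors)
        true_activity.append(frames_active)

        track = Track(track_id=person, state="confirmed")
        for t in range(n_frames):
            kp = _stance(anchors[t, 0], anchors[t, 1])
            track.poses[t] = PoseFrame(frame_index=t, keypoints=kp, person_hypothesis_id=person)
        track.last_seen = n_frames - 1
        true_tracks.append(track)

    detections: list[PoseFrame] = []
    for t in range(n_frames):
        for person in range(config.n_staff):
            kp = true_tracks[person].poses[t].keypoints.copy()
            if config.jitter_sd > 0:
                kp[:, :2] += rng.normal(0.0, config.jitter_sd, size=(17, 2))
            conf = rng.uniform(0.75, 0.98, size=17)
            if config.low_conf_rate > 0 and rng.random() < config.low_conf_rate:
                conf *= 0.3
            kp[:, 2] = conf
            if config.dropout_rate > 0:
                drop = rng.random(17) < config.dropout_rate
                kp[drop] = np.nan
            if np.isnan(kp).all():
                continue
            detections.append(
                PoseFrame(frame_index=t, keypoints=kp, person_hypothesis_id=person)
            )

    return detections, GroundTruth(true_tracks, true_activity, timeline)


def tracks_from_truth(detections: Sequence[PoseFrame], n_staff: int) -> list[Track]:
    """Group detections into tracks by their true person id (oracle tracking)."""
    tracks = [Track(track_id=p, state="confirmed") for p in range(n_staff)]
    for det in detections:
        p = det.person_hypothesis_id
        if p is None:
            continue
        tracks[p].poses[det.frame_index] = det
        tracks[p].last_seen = max(tracks[p].last_seen, det.frame_index)
    return [t for t in tracks if t.poses]


# ---------------------------------------------------------------------------
# Questionnaire simulation
# ---------------------------------------------------------------------------

# Per-(domain, surgery type) means and SDs on the phase-sum (0-60) scale.
# The four domains with published descriptive statistics use those values;
# the remaining three use plausible mid-range values following the same
# robotics-elevated pattern.
_TYPE_LEVEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "mental": {"OS": (18.95, 10.96), "MIS": (16.00, 10.42), "RAS": (22.58, 11.41)},
    "temporal": {"OS": (20.26, 11.39), "MIS": (19.68, 10.27), "RAS": (25.37, 12.43)},
    "distractions": {"OS": (16.16, 10.87), "MIS": (16.84, 10.23), "RAS": (23.05, 14.40)},
    "satisfaction": {"OS": (46.47, 8.53), "MIS": (34.53, 13.83), "RAS": (31.95, 14.27)},
    "physical": {"OS": (18.0, 11.0), "MIS": (15.0, 11.0), "RAS": (20.0, 11.0)},
    "complexity": {"OS": (17.0, 11.0), "MIS": (16.0, 11.0), "RAS": (21.0, 11.0)},
    "stress": {"OS": (16.0, 11.0), "MIS": (15.0, 11.0), "RAS": (20.0, 11.0)},
}

# Mental demand varies by phase (type-summed means 16.42 / 22.68 / 18.42);
# expressed as multiplicative phase weights with mean 1.
_MENTAL_PHASE_WEIGHTS = {1: 0.8565, 2: 1.1830, 3: 0.9609}


def default_surgtlx_params(respondent_corr: float = 0.6) -> pd.DataFrame:
    """Per-cell normal parameters on the single-phase 0-20 scale.

    Phase means are one third of the type-level mean (phase-modulated for
    mental demand). Phase SDs are chosen so that summing the three phases
    of one respondent reproduces the type-level SD before clamping: with a
    between-cell correlation rho inside a respondent,
    Var(sum of 3) = 3 sd_phase^2 (1 + 2 rho), hence
    sd_phase = sd_type / sqrt(3 (1 + 2 rho)).
    """
    scale = math.sqrt(3.0 * (1.0 + 2.0 * respondent_corr))
    rows = []
    for domain in SURGTLX_DOMAINS:
        for stype in SURGERY_TYPES:
            mean60, sd60 = _TYPE_LEVEL_PARAMS[domain][stype]
            for phase in PHASES:
                w = _MENTAL_PHASE_WEIGHTS[phase] if domain == "mental" else 1.0
                rows.append(
                    {
                        "domain": domain,
                        "surgery_type": stype,
                        "phase": phase,
                        "mean": mean60 / 3.0 * w,
                        "sd": sd60 / scale,
                    }
                )
    return pd.DataFrame(rows)


class SurgTlxSimConfig(BaseModel):
    """Questionnaire simulator configuration.

    ``params`` holds per-cell (domain, surgery_type, phase) normal means and
    SDs on the 0-20 scale; defaults come from
    :func:`default_surgtlx_params`. ``respondent_corr`` is the correlation
    between any two cells of one respondent, realised as a respondent-level
    random intercept with the marginal SDs preserved — repeated-measures
    questionnaire data shows substantial rater-level consistency, and the
    within-subject design depends on it.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_respondents: int
    params: Optional[pd.DataFrame] = None
    missing_rate: float = 0.0
    respondent_corr: float = 0.6
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.respondent_corr < 1.0:
            raise ValueError("respondent_corr must be in [0, 1)")
        if self.params is not None:
            means = self.params["mean"]
            if ((means < 0) | (means > SCALE_MAX)).any():
                raise ValueError(f"means must lie in [0, {SCALE_MAX:g}]")
            if (self.params["sd"] < 0).any():
                raise ValueError("sds must be >= 0")
        return self


def simulate_surgtlx(config: SurgTlxSimConfig) -> pd.DataFrame:
    """Draw questionnaire responses in long format.

    Each cell score is normal with the configured mean/SD (plus the shared
    respondent intercept), then clamped to the instrument's [0, 20] scale.
    Clamping rather than resampling keeps the generator monotone in the
    mean, at the cost of a bias toward mid-scale for extreme means.
    Respondents flagged incomplete (probability ``missing_rate``) have at
    least one missing cell. Deterministic given ``config.seed``.
    """
    params = (
        config.params
        if config.params is not None
        else default_surgtlx_params(config.respondent_corr)
    )
    rng = np.random.default_rng(config.seed)
    rho = config.respondent_corr
    cells = params.sort_values(["domain", "surgery_type", "phase"]).reset_index(drop=True)
    n_cells = len(cells)

    frames = []
    for r in range(config.n_respondents):
        z = rng.normal()  # respondent intercept on the standard scale
        eps = rng.normal(size=n_cells)
        raw = cells["mean"].to_numpy() + cells["sd"].to_numpy() * (
            math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
        )
        scores = np.clip(raw, 0.0, SCALE_MAX)
        incomplete = rng.random() < config.missing_rate
        if incomplete:
            miss = rng.random(n_cells) < 0.3
            if not miss.any():
                miss[rng.integers(n_cells)] = True
            scores = scores.astype(float)
            scores[miss] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": f"R{r:03d}",
                    "domain": cells["domain"],
                    "surgery_type": cells["surgery_type"],
                    "phase": cells["phase"],
                    "score": scores,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["respondent_id", "domain", "surgery_type", "phase", "score"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Schedule simulation
# ---------------------------------------------------------------------------


class ScheduleSimConfig(BaseModel):
    """Hospital schedule simulator configuration.

    Planned phase durations (minutes) and signed deviation means per type
    default to the qualitative pattern of a gynecology OR programme: open
    procedures tend to finish early, minimally invasive ones run close to
    plan with the shortest totals, robotic-assisted ones run long with the
    longest cutting phases, higher patient risk in open surgery and more
    staff for open/robotic procedures.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_procedures: int
    type_mix: tuple[float, float, float] = (0.2, 0.55, 0.25)  # OS, MIS, RAS
    planned_means: dict[str, tuple[float, float, float]] = {
        "OS": (30.0, 90.0, 25.0),
        "MIS": (25.0, 60.0, 20.0),
        "RAS": (35.0, 95.0, 25.0),
    }
    deviation_means: dict[str, tuple[float, float, float]] = {
        "OS": (-1.0, -6.0, -1.0),
        "MIS": (0.0, 1.0, 0.0),
        "RAS": (2.0, 6.0, 2.0),
    }
    deviation_sd_frac: float = 0.15
    risk_probs: dict[str, tuple[float, float, float, float]] = {
        "OS": (0.15, 0.35, 0.35, 0.15),
        "MIS": (0.30, 0.45, 0.20, 0.05),
        "RAS": (0.40, 0.45, 0.13, 0.02),
    }
    staff_means: dict[str, float] = {"OS": 7.0, "MIS": 5.0, "RAS": 7.0}
    emergency_rates: dict[str, float] = {"OS": 0.15, "MIS": 0.05, "RAS": 0.01}
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_procedures < 0:
            raise ValueError("n_procedures must be >= 0")
        if any(p < 0 for p in self.type_mix) or not math.isclose(sum(self.type_mix), 1.0):
            raise ValueError("type_mix proportions must be >= 0 and sum to 1")
        if self.deviation_sd_frac < 0:
            raise ValueError("deviation_sd_frac must be >= 0")
        return self


def simulate_schedule(config: ScheduleSimConfig) -> pd.DataFrame:
    """Generate procedure schedule records; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    rows = []
    types = rng.choice(SURGERY_TYPES, size=config.n_procedures, p=list(config.type_mix))
    for i, stype in enumerate(types):
        planned = np.array(config.planned_means[stype], dtype=float)
        planned = planned * rng.uniform(0.85, 1.15, size=3)
        dev = np.array(config.deviation_means[stype], dtype=float)
        actual = planned + dev + rng.normal(0.0, config.deviation_sd_frac * planned)
        actual = np.maximum(actual, 1.0)
        risk = int(rng.choice([1, 2, 3, 4], p=list(config.risk_probs[stype])))
        staff = max(1, int(round(rng.normal(config.staff_means[stype], 0.8))))
        rows.append(
            {
                "procedure_id": f"P{i:04d}",
                "surgery_type": stype,
                "planned_phase1": round(planned[0], 1),
                "planned_phase2": round(planned[1], 1),
                "planned_phase3": round(planned[2], 1),
                "actual_phase1": round(actual[0], 1),
                "actual_phase2": round(actual[1], 1),
                "actual_phase3": round(actual[2], 1),
                "risk_class": risk,
                "emergency": bool(rng.random() < config.emergency_rates[stype]),
                "staff_count": staff,
            }
        )
    columns = [
        "procedure_id", "surgery_type",
        "planned_phase1", "planned_phase2", "planned_phase3",
        "actual_phase1", "actual_phase2", "actual_phase3",
        "risk_class", "emergency", "staff_count",
    ]
    return pd.DataFrame(rows, columns=columns)
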