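"""Phase-level activity, movement and interaction percentages.

Three descriptive quantities summarise how staff use the operating table
over the three clinical phases:

* **activity percentage** — combined active person-time in a phase relative
  to the *average* duration of that phase across procedures of the same
  surgery type (so phases of unequal length compare fairly; with several
  staff active simultaneously the value may exceed 100%);
* **interaction percentage** — the same combined occupancy relative to the
  phase duration of the procedure itself;
* **movement percentage** — the fraction of tracked time a person's
  shoulder/head displacement exceeds the walking threshold, averaged over
  persons.

Undetermined frames (keypoint dropout, warm-up) are excluded from both the
numerator and the denominator: each person's occupancy is estimated as the
active fraction among their determined frames, scaled by their tracked
time. At full determination this reduces to a plain frame count, and under
random dropout it is unbiased rather than systematically low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ACTIVE, INACTIVE, ActivityParams, ActivitySeries, displacement
from .io import PHASES, PhaseTimeline


def _estimated_active_frames(series: ActivitySeries, lo: int, hi: int) -> float:
    """Estimated active frame count of one person within [lo, hi).

    The active fraction is factored into the zone-pass fraction (among
    frames where the zone test is determined) times the non-vetoed fraction
    (among zone-pass frames with a determined displacement), each estimated
    on its own determined subset. Under keypoint dropout the two subsets
    shrink at different rates — active frames need more keypoints than
    zone-fail frames — so a single pooled active/determined ratio would be
    biased low, while both factors here are conditionally unbiased. With no
    undetermined frames this reduces to a plain active-frame count.
    """
    in_phase = (series.frames >= lo) & (series.frames < hi)
    status = series.status[in_phase]
    zone = series.zone[in_phase]
    n_pose = int(in_phase.sum())
    n_pass = int((zone == "pass").sum())
    n_fail = int((zone == "fail").sum())
    if n_pass + n_fail == 0 or n_pass == 0:
        return 0.0
    pass_frac = n_pass / (n_pass + n_fail)
    n_active = int((status == ACTIVE).sum())
    n_veto = int(((zone == "pass") & (status == INACTIVE)).sum())
    if n_active + n_veto == 0:
        return 0.0
    keep_frac = n_active / (n_active + n_veto)
    return pass_frac * keep_frac * n_pose


def activity_percentage(
    series: Sequence[ActivitySeries],
    timeline: PhaseTimeline,
    mean_phase_frames: Optional[Mapping[int, float]] = None,
) -> dict[int, float]:
    """Combined activity percentage per phase.

    ``mean_phase_frames`` is the average phase duration (in frames) across
    procedures of the same surgery type; when omitted the procedure's own
    phase durations are used (which makes this identical to
    :func:`interaction_percentage`).
    """
    out: dict[int, float] = {}
    for phase in PHASES:
        lo, hi = timeline.phase_bounds(phase)
        denom = float(mean_phase_frames[phase]) if mean_phase_frames else float(hi - lo)
        if denom <= 0:
            raise ValueError(f"mean duration of phase {phase} must be > 0")
        total = sum(_estimated_active_frames(s, lo, hi) for s in series)
        out[phase] = 100.0 * total / denom
    return out


def interaction_percentage(
    series: Sequence[ActivitySeries], timeline: PhaseTimeline
) -> dict[int, float]:
    """Combined table-area occupancy per phase, relative to the procedure's
    own phase duration. May exceed 100% when several staff are active."""
    for phase in PHASES:
        lo, hi = timeline.phase_bounds(phase)
        if hi <= lo:
            raise ValueError(f"phase {phase} has zero length")
    return activity_percentage(series, timeline, mean_phase_frames=None)


def movement_percentage(
    tracks,
    params: ActivityParams | None = None,
    frame_range: Optional[tuple[int, int]] = None,
    pooled: bool = False,
) -> Optional[float]:
    """Percentage of tracked time spent moving faster than the threshold.

    Per person: frames whose shoulder/head displacement exceeds the
    threshold, divided by frames with a determined displacement; averaged
    across persons (or pooled over person-frames with ``pooled=True``).
    Returns None when no frame has a determined displacement.
    """
    params = params or ActivityParams()
    per_person: list[tuple[int, int]] = []
    for tr in tracks:
        moving = determined = 0
        for t in tr.poses:
            if frame_range is not None and not frame_range[0] <= t < frame_range[1]:
                continue
            disp = displacement(tr, t, params.window, params.min_confidence, params.aggregator)
            if disp is None:
                continue
            determined += 1
            if disp > params.displacement_threshold:
                moving += 1
        if determined > 0:
            per_person.append((moving, determined))
    if not per_person:
        return None
    if pooled:
        moving = sum(m for m, _ in per_person)
        determined = sum(d for _, d in per_person)
        return 100.0 * moving / determined
    return float(np.mean([100.0 * m / d for m, d in per_person]))


def procedure_metrics(
    series: Sequence[ActivitySeries],
    tracks,
    timeline: PhaseTimeline,
    params: ActivityParams | None = None,
    mean_phase_frames: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Per-phase metrics table for one procedure."""
    params = params or ActivityParams()
    act = activity_percentage(series, timeline, mean_phase_frames)
    inter = interaction_percentage(series, timeline)
    rows = []
    for phase in PHASES:
        move = movement_percentage(tracks, params, frame_range=timeline.phase_bounds(phase))
        rows.append(
            {
                "procedure_id": timeline.procedure_id,
                "surgery_type": timeline.surgery_type,
                "phase": phase,
                "activity_pct": act[phase],
                "movement_pct": move,
                "interaction_pct": inter[phase],
            }
        )
    return pd.DataFrame(rows)


def summarize(per_procedure: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics across procedures within surgery type and phase."""
    if per_procedure.empty:
        raise ValueError("no procedures to summarize")
    value_cols = [c for c in ("activity_pct", "movement_pct", "interaction_pct")
                  if c in per_procedure.columns]
    grouped = per_procedure.groupby(["surgery_type", "phase"], sort=True)
    summary = grouped[value_cols].mean()
    summary["n_procedures"] = grouped["procedure_id"].nunique()
    return summary.reset_index()


def plot_phase_metrics(summary: pd.DataFrame, value: str = "activity_pct", ax=None):
    """Grouped bar chart of a summary metric by phase and surgery type."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    pivot = summary.pivot(index="phase", columns="surgery_type", values=value)
    pivot.plot.bar(ax=ax, rot=0)
    ax.set_xlabel("Surgical phase")
    ax.set_ylabel(value.replace("_pct", " (%)").replace("_", " "))
    ax.legend(title="Surgery type")
    return ax
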