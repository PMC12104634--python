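"""Hospital schedule context metrics.

Planned-versus-actual phase deviations (signed minutes; negative means the
phase finished early), "dark time" (the period with dimmed room lights,
which in minimally invasive and robotic-assisted procedures is essentially
the cutting phase — proxied by the actual phase-2 duration unless the
record carries a dedicated ``dark_time`` field), and grouped summaries of
durations, risk classes and staffing per surgery type.

Only complete cases (all planned and actual durations present) enter the
summaries; records excluded this way are counted, not imputed.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

PHASE_COLS = [("planned_phase" + str(p), "actual_phase" + str(p)) for p in (1, 2, 3)]
_REQUIRED = [c for pair in PHASE_COLS for c in pair]


def complete_schedule_cases(records: pd.DataFrame) -> pd.DataFrame:
    """Records with all planned and actual phase durations present."""
    return records.dropna(subset=_REQUIRED).copy()


def deviation(records: pd.DataFrame) -> pd.DataFrame:
    """Signed actual-minus-planned deviation per phase and in total (minutes).

    Records missing any duration are excluded (complete-case rule).
    """
    out = complete_schedule_cases(records)
    for p, (planned, actual) in zip((1, 2, 3), PHASE_COLS):
        out[f"deviation_phase{p}"] = out[actual] - out[planned]
    out["deviation_total"] = sum(out[f"deviation_phase{p}"] for p in (1, 2, 3))
    return out


def dark_time(records: pd.DataFrame) -> pd.Series:
    """Dark time per record, minutes.

    Uses the record's ``dark_time`` column when present; otherwise the
    actual phase-2 (cutting-phase) duration. Records without phase-2 data
    are excluded.
    """
    if "dark_time" in records.columns:
        series = records["dark_time"].dropna()
    else:
        series = records["actual_phase2"].dropna()
    series = series.astype(float)
    if (series < 0).any():
        raise ValueError("dark time cannot be negative")
    return series


def summarize_schedule(records: pd.DataFrame) -> pd.DataFrame:
    """Per-surgery-type summary of durations, deviations, risk and staffing.

    Complete cases only; the number of excluded records is logged and kept
    in ``DataFrame.attrs['n_excluded']``.
    """
    if records.empty:
        raise ValueError("no schedule records to summarize")
    complete = complete_schedule_cases(records)
    n_excluded = len(records) - len(complete)
    if n_excluded:
        logger.info("summarize_schedule: excluded %d incomplete records", n_excluded)
    if complete.empty:
        raise ValueError("no complete schedule records to summarize")
    dev = deviation(complete)
    dev["total_actual"] = sum(dev[f"actual_phase{p}"] for p in (1, 2, 3))
    dev["dark_time_min"] = dark_time(dev)

    grouped = dev.groupby("surgery_type")
    summary = grouped.agg(
        n=("procedure_id", "count"),
        mean_total_duration=("total_actual", "mean"),
        mean_deviation_phase1=("deviation_phase1", "mean"),
        mean_deviation_phase2=("deviation_phase2", "mean"),
        mean_deviation_phase3=("deviation_phase3", "mean"),
        mean_deviation_total=("deviation_total", "mean"),
        mean_dark_time=("dark_time_min", "mean"),
        mean_risk_class=("risk_class", "mean"),
        mean_staff_count=("staff_count", "mean"),
        emergency_rate=("emergency", "mean"),
    ).reset_index()

    risk_dist = (
        dev.groupby(["surgery_type", "risk_class"]).size().unstack(fill_value=0)
    )
    risk_dist = risk_dist.div(risk_dist.sum(axis=1), axis=0)
    for cls in risk_dist.columns:
        summary[f"risk_class_{cls}_frac"] = summary["surgery_type"].map(risk_dist[cls])

    summary.attrs["n_excluded"] = n_excluded
    return summary
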