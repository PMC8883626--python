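"""Chrono-nutrition behaviours from timestamped one-day food records.

Two behaviours are derived per record: the eating window (hours between the
first and last timed consumption of any food or drink) and breakfast
consumer status (>= 100 kcal consumed strictly between 06:00 and 11:00).
Records with an eating window under 4 h are treated as implausibly recorded
and dropped from behaviour analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import parse_clock_time

__all__ = [
    "eating_window",
    "classify_breakfast",
    "behaviour_table",
    "filter_implausible_windows",
]

BREAKFAST_START_MIN = 6 * 60  # exclusive
BREAKFAST_END_MIN = 11 * 60  # exclusive
BREAKFAST_KCAL_FLOOR = 100.0  # inclusive
MIN_PLAUSIBLE_WINDOW_H = 4.0


def _timed_minutes(entries: pd.DataFrame) -> np.ndarray:
    times = [parse_clock_time(t) for t in entries["meal_time"]]
    return np.array([t for t in times if t is not None], dtype=float)


def eating_window(entries: pd.DataFrame) -> float:
    """Hours from first to last timed entry; NaN if no entry has a time."""
    mins = _timed_minutes(entries)
    if len(mins) == 0:
        return float("nan")
    return float((mins.max() - mins.min()) / 60.0)


def classify_breakfast(entries: pd.DataFrame) -> bool:
    """True iff energy timed strictly within (06:00, 11:00) totals >= 100 kcal.

    The floor applies to the summed energy of all qualifying entries, not to
    any single eating occasion; untimed entries contribute nothing.
    """
    total = 0.0
    for t, kcal in zip(entries["meal_time"], entries["energy_kcal"]):
        mins = parse_clock_time(t)
        if mins is not None and BREAKFAST_START_MIN < mins < BREAKFAST_END_MIN:
            total += float(kcal)
    return total >= BREAKFAST_KCAL_FLOOR


def behaviour_table(entries: pd.DataFrame) -> pd.DataFrame:
    """Per-record behaviour summary.

    Columns: record_id, participant_id, first_intake / last_intake (minutes
    since midnight), eating_window (h), pre11_energy (kcal),
    breakfast_consumer.  Records with no timed entry get NaN window and are
    dropped by downstream filters.
    """
    rows = []
    for rid, grp in entries.groupby("record_id", sort=True):
        mins = _timed_minutes(grp)
        pre11 = sum(
            float(k)
            for t, k in zip(grp["meal_time"], grp["energy_kcal"])
            if (m := parse_clock_time(t)) is not None
            and BREAKFAST_START_MIN < m < BREAKFAST_END_MIN
        )
        rows.append(
            {
                "record_id": rid,
                "participant_id": grp["participant_id"].iloc[0],
                "first_intake": mins.min() if len(mins) else np.nan,
                "last_intake": mins.max() if len(mins) else np.nan,
                "eating_window": (mins.max() - mins.min()) / 60.0 if len(mins) else np.nan,
                "pre11_energy": pre11,
                "breakfast_consumer": pre11 >= BREAKFAST_KCAL_FLOOR,
            }
        )
    return pd.DataFrame(rows)


def filter_implausible_windows(
    summaries: pd.DataFrame, floor_h: float = MIN_PLAUSIBLE_WINDOW_H
) -> pd.DataFrame:
    """Drop records whose eating window is missing or strictly below ``floor_h``."""
    keep = summaries["eating_window"] >= floor_h  # NaN compares False
    return summaries.loc[keep].reset_index(drop=True)
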