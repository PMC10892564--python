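"""Per-day digital biomarkers from cleaned minute streams.

Implements outlier removal (minutes whose step count exceeds the cutoff are
dropped), daily step totals, the peak single-minute cadence, the peak mean
cadence over any six consecutive minutes, cadence-band intensity minutes, and
weekly intensity aggregation.

Conventions (all configurable through :class:`IntensityThresholds`):

* a minute with steps strictly greater than ``outlier_cutoff`` (default 150)
  is an outlier; a minute at exactly the cutoff is retained;
* intensity bands are half-open on the right — sedentary ``[0, 20)``, light
  ``[20, 100)``, moderate ``[100, 130)``, vigorous ``[130, cutoff]`` — so a
  minute at exactly 100 steps counts as moderate;
* minutes absent from the stream count as 0 steps inside 6-minute windows
  (inactivity), but windows containing an outlier-removed minute are invalid
  (measurement error must not masquerade as rest).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stream_model import DaySummary

__all__ = [
    "IntensityThresholds",
    "CleanedDayStream",
    "remove_outliers",
    "daily_steps",
    "peak_1min",
    "peak_6min_consecutive",
    "intensity_minutes",
    "weekly_intensity",
    "summarize_day",
    "summarize_cohort",
    "P6MC_WINDOW",
]

P6MC_WINDOW = 6


@dataclass(frozen=True)
class IntensityThresholds:
    """Cadence thresholds (steps/min) separating intensity bands."""

    sedentary_upper: float = 20.0
    moderate_lower: float = 100.0
    vigorous_lower: float = 130.0
    outlier_cutoff: float = 150.0

    def __post_init__(self) -> None:
        if not (
            0
            < self.sedentary_upper
            < self.moderate_lower
            < self.vigorous_lower
            <= self.outlier_cutoff
        ):
            raise ValueError(
                "thresholds must satisfy 0 < sedentary_upper < moderate_lower "
                "< vigorous_lower <= outlier_cutoff"
            )


DEFAULT_THRESHOLDS = IntensityThresholds()


@dataclass(frozen=True)
class CleanedDayStream:
    """One patient-day after outlier removal.

    ``minute_of_day`` and ``steps`` are parallel arrays sorted strictly
    increasing by minute; ``removed_minutes`` holds the minutes excluded as
    outliers.
    """

    patient_id: str
    date: dt.date
    minute_of_day: np.ndarray
    steps: np.ndarray
    removed_minutes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.minute_of_day) != len(self.steps):
            raise ValueError("minute_of_day and steps must be parallel arrays")
        if len(self.minute_of_day) > 1 and not np.all(np.diff(self.minute_of_day) > 0):
            raise ValueError("minutes must be sorted strictly increasing")

    def __len__(self) -> int:
        return len(self.minute_of_day)


def _as_arrays(
    minutes: Sequence[tuple[int, int]] | tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    if (
        isinstance(minutes, tuple)
        and len(minutes) == 2
        and isinstance(minutes[0], np.ndarray)
    ):
        mins, steps = minutes
    else:
        pairs = list(minutes)
        if not pairs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        mins = np.asarray([p[0] for p in pairs], dtype=np.int64)
        steps = np.asarray([p[1] for p in pairs], dtype=np.int64)
    order = np.argsort(mins, kind="stable")
    return mins[order], steps[order]


def remove_outliers(
    minutes: Sequence[tuple[int, int]] | tuple[np.ndarray, np.ndarray],
    patient_id: str = "",
    date: dt.date = dt.date(1970, 1, 1),
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
) -> CleanedDayStream:
    """Drop minutes whose step count exceeds the outlier cutoff.

    Idempotent; retained values are never altered.  A minute at exactly the
    cutoff is retained.
    """
    mins, steps = _as_arrays(minutes)
    keep = steps <= thresholds.outlier_cutoff
    removed = frozenset(int(m) for m in mins[~keep])
    return CleanedDayStream(
        patient_id=patient_id,
        date=date,
        minute_of_day=mins[keep],
        steps=steps[keep],
        removed_minutes=removed,
    )


def daily_steps(stream: CleanedDayStream) -> int:
    """Total steps over retained minutes (0 for an empty stream)."""
    return int(stream.steps.sum())


def peak_1min(stream: CleanedDayStream) -> float:
    """Highest step count in any retained minute; NaN when no minute remains."""
    if len(stream) == 0:
        return float("nan")
    return float(stream.steps.max())


def peak_6min_consecutive(stream: CleanedDayStream, window: int = P6MC_WINDOW) -> float:
    """Highest mean cadence over ``window`` consecutive minutes of the day.

    Window starts range over the recorded span of the day (every start
    ``j`` with ``first_minute <= j <= last_minute - window + 1``).  Minutes
    absent from the stream count as 0 steps; windows overlapping an
    outlier-removed minute are invalid.  Returns NaN when no valid window
    exists.
    """
    removed = np.fromiter(stream.removed_minutes, dtype=np.int64, count=len(stream.removed_minutes))
    if len(stream) == 0 and removed.size == 0:
        return float("nan")
    all_minutes = (
        np.concatenate([stream.minute_of_day, removed]) if removed.size else stream.minute_of_day
    )
    lo = int(all_minutes.min())
    hi = int(all_minutes.max())
    span = hi - lo + 1
    if span < window:
        return float("nan")
    dense = np.zeros(span, dtype=np.float64)
    dense[stream.minute_of_day - lo] = stream.steps
    kernel = np.ones(window)
    sums = np.convolve(dense, kernel, mode="valid")
    if removed.size:
        bad = np.zeros(span, dtype=np.float64)
        bad[removed - lo] = 1.0
        invalid = np.convolve(bad, kernel, mode="valid") > 0
        if invalid.all():
            return float("nan")
        sums = sums[~invalid]
    return float(sums.max() / window)


def intensity_minutes(
    stream: CleanedDayStream, thresholds: IntensityThresholds = DEFAULT_THRESHOLDS
) -> tuple[int, int, int, int]:
    """Count retained minutes per band: (sedentary, light, moderate, vigorous).

    Bands are half-open on the right, so a minute at exactly a lower threshold
    falls in the higher band.  The four counts always partition the retained
    minutes.
    """
    edges = np.array(
        [thresholds.sedentary_upper, thresholds.moderate_lower, thresholds.vigorous_lower]
    )
    idx = np.searchsorted(edges, stream.steps, side="right")
    counts = np.bincount(idx, minlength=4)
    return int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3])


def summarize_day(
    patient_id: str,
    date: dt.date,
    day_post_op: int,
    minutes: Sequence[tuple[int, int]] | tuple[np.ndarray, np.ndarray],
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
) -> DaySummary:
    """Outlier-clean one patient-day and compute every biomarker."""
    stream = remove_outliers(minutes, patient_id, date, thresholds)
    sed, light, mod, vig = intensity_minutes(stream, thresholds)
    return DaySummary(
        patient_id=patient_id,
        date=date,
        day_post_op=day_post_op,
        steps=daily_steps(stream),
        p1m=peak_1min(stream),
        p6mc=peak_6min_consecutive(stream),
        min_sedentary=sed,
        min_light=light,
        min_moderate=mod,
        min_vigorous=vig,
        n_minutes_recorded=len(stream),
        n_outliers_removed=len(stream.removed_minutes),
    )


def summarize_cohort(
    minutes: pd.DataFrame, thresholds: IntensityThresholds = DEFAULT_THRESHOLDS
) -> list[DaySummary]:
    """Summarize every patient-day in an aligned minute frame.

    ``minutes`` must carry columns ``patient_id, date, minute_of_day, steps,
    day_post_op`` (see :func:`cadencelab.stream_model.align_to_surgery`).
    """
    required = {"patient_id", "date", "minute_of_day", "steps", "day_post_op"}
    missing = required - set(minutes.columns)
    if missing:
        raise ValueError(f"minute frame missing columns {sorted(missing)}")
    out: list[DaySummary] = []
    cols = ["minute_of_day", "steps"]
    for (pid, date, dpo), grp in minutes.groupby(
        ["patient_id", "date", "day_post_op"], sort=True
    ):
        m = grp[cols[0]].to_numpy(dtype=np.int64)
        s = grp[cols[1]].to_numpy(dtype=np.int64)
        date = date if isinstance(date, dt.date) else pd.Timestamp(date).date()
        out.append(summarize_day(str(pid), date, int(dpo), (m, s), thresholds))
    return out


def weekly_intensity(
    day_summaries: Iterable[DaySummary] | pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate one patient's intensity minutes into post-op weeks.

    Week ``k`` (k >= 1) covers ``day_post_op`` 7k-6 .. 7k.  Weeks with no
    recorded day are absent; weeks with fewer than 7 days carry
    ``complete == False``.  Returns columns ``week_index, min_light,
    min_moderate, min_vigorous, n_days, complete``.
    """
    if not isinstance(day_summaries, pd.DataFrame):
        from .stream_model import day_summaries_to_frame

        day_summaries = day_summaries_to_frame(list(day_summaries))
    df = day_summaries[day_summaries["day_post_op"] >= 1].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["week_index", "min_light", "min_moderate", "min_vigorous", "n_days", "complete"]
        )
    if df["patient_id"].nunique() > 1:
        raise ValueError("weekly_intensity aggregates a single patient")
    df["week_index"] = (df["day_post_op"] + 6) // 7
    agg = (
        df.groupby("week_index")
        .agg(
            min_light=("min_light", "sum"),
            min_moderate=("min_moderate", "sum"),
            min_vigorous=("min_vigorous", "sum"),
            n_days=("day_post_op", "size"),
        )
        .reset_index()
    )
    agg["complete"] = agg["n_days"] >= 7
    return agg
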