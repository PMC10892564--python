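"""Intraweek variability of daily biomarkers.

The coefficient of variation (sample SD / mean) of each metric is computed
across the days of each surgery-anchored post-operative week, per patient,
then aggregated across the cohort as median [p25; p75] per week.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CV_METRICS", "intraweek_cv", "patient_week_cv", "cohort_cv_profile"]

CV_METRICS = ("steps", "p1m", "p6mc")

DEFAULT_MIN_DAYS = 4


def intraweek_cv(values: Sequence[float] | np.ndarray, min_days: int = DEFAULT_MIN_DAYS) -> float:
    """Coefficient of variation of up to 7 daily values.

    Sample (n-1) standard deviation divided by the mean.  Returns NaN when
    fewer than ``min_days`` finite values are available or the mean is not
    strictly positive.
    """
    arr = np.asarray(values, dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_days:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def patient_week_cv(
    day_summaries: pd.DataFrame,
    metrics: Iterable[str] = CV_METRICS,
    min_days: int = DEFAULT_MIN_DAYS,
) -> pd.DataFrame:
    """Per patient x post-op week x metric CV table.

    Weeks use the surgery-anchored binning of ``weekly_intensity`` (week k
    covers day_post_op 7k-6..7k).  Rows whose CV is undefined are dropped.
    Returns columns ``patient_id, week_index, metric, cv, n_days``.
    """
    df = day_summaries[day_summaries["day_post_op"] >= 1].copy()
    df["week_index"] = (df["day_post_op"] + 6) // 7
    rows = []
    for (pid, week), grp in df.groupby(["patient_id", "week_index"], sort=True):
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            cv = intraweek_cv(vals, min_days=min_days)
            if not math.isnan(cv):
                rows.append((pid, int(week), metric, cv, int(vals.size)))
    return pd.DataFrame(rows, columns=["patient_id", "week_index", "metric", "cv", "n_days"])


def cohort_cv_profile(
    day_summaries: pd.DataFrame,
    metrics: Iterable[str] = CV_METRICS,
    min_days: int = DEFAULT_MIN_DAYS,
) -> pd.DataFrame:
    """Cohort-level weekly CV profile: median and interquartile range.

    Aggregation is per-patient-then-median: each patient contributes one CV
    per week and metric, and the cohort summary is the median [p25; p75] of
    those per-patient values.  Returns columns ``metric, week_index,
    median_cv, p25_cv, p75_cv, n_patients``.
    """
    per_patient = patient_week_cv(day_summaries, metrics=metrics, min_days=min_days)
    if per_patient.empty:
        raise ValueError("no patient-week has enough days for a CV")
    agg = (
        per_patient.groupby(["metric", "week_index"])["cv"]
        .agg(
            median_cv="median",
            p25_cv=lambda s: float(np.percentile(s, 25)),
            p75_cv=lambda s: float(np.percentile(s, 75)),
            n_patients="size",
        )
        .reset_index()
    )
    return agg
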