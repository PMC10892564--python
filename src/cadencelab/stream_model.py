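"""Data model and I/O for minute-level step streams and patient metadata.

The atoms are :class:`MinuteRecord` (one minute of one patient-day),
:class:`PatientMeta` (demographics, surgery descriptors, outcome scores) and
:class:`DaySummary` (per-day derived biomarkers).  Bulk operations use pandas
DataFrames with the same column names; the dataclasses carry the validation
contracts.

Minutes absent from a stream mean "no data recorded" — they are never imputed
as zero at this layer.  Duplicate (patient, date, minute) rows are a hard
error so upstream export bugs surface immediately.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MinuteRecord",
    "PatientMeta",
    "DaySummary",
    "Cohort",
    "MINUTE_COLUMNS",
    "METADATA_COLUMNS",
    "DAY_SUMMARY_COLUMNS",
    "read_minute_csv",
    "read_metadata_csv",
    "minute_records_to_frame",
    "frame_to_minute_records",
    "align_to_surgery",
    "write_day_summaries",
    "read_day_summaries",
    "day_summaries_to_frame",
    "write_minute_frame",
    "write_metadata",
]

MINUTE_COLUMNS = ["patient_id", "date", "minute_of_day", "steps"]
METADATA_COLUMNS = [
    "patient_id",
    "joint",
    "surgery_type",
    "surgery_date",
    "age",
    "gender",
    "bmi",
    "fjs_pre",
    "fjs_3m",
]
DAY_SUMMARY_COLUMNS = [
    "patient_id",
    "date",
    "day_post_op",
    "steps",
    "p1m",
    "p6mc",
    "min_sedentary",
    "min_light",
    "min_moderate",
    "min_vigorous",
    "n_minutes_recorded",
    "n_outliers_removed",
]

VALID_JOINTS = frozenset({"hip", "knee"})
VALID_SURGERY_TYPES = frozenset({"total", "unicondylar", "revision", "resurfacing"})
VALID_GENDERS = frozenset({"female", "male"})

# joint-specific procedures: partial (unicondylar) knees and resurfaced hips only
_JOINT_ONLY = {"unicondylar": "knee", "resurfacing": "hip"}


class StreamValidationError(ValueError):
    """Raised when an input file violates the minute-stream or metadata schema."""


@dataclass(frozen=True)
class MinuteRecord:
    """One minute of one patient-day with a non-negative step count."""

    patient_id: str
    date: dt.date
    minute_of_day: int
    steps: int

    def __post_init__(self) -> None:
        if not (0 <= self.minute_of_day <= 1439):
            raise StreamValidationError(
                f"minute_of_day must be in [0, 1439], got {self.minute_of_day}"
            )
        if self.steps < 0:
            raise StreamValidationError(f"steps must be >= 0, got {self.steps}")


@dataclass(frozen=True)
class PatientMeta:
    """Demographics, surgery descriptors and Forgotten Joint Scores."""

    patient_id: str
    joint: str
    surgery_type: str
    surgery_date: dt.date
    age: float
    gender: str
    bmi: float
    fjs_pre: float | None = None
    fjs_3m: float | None = None

    def __post_init__(self) -> None:
        if self.joint not in VALID_JOINTS:
            raise StreamValidationError(f"unknown joint {self.joint!r}")
        if self.surgery_type not in VALID_SURGERY_TYPES:
            raise StreamValidationError(f"unknown surgery_type {self.surgery_type!r}")
        required_joint = _JOINT_ONLY.get(self.surgery_type)
        if required_joint is not None and self.joint != required_joint:
            raise StreamValidationError(
                f"surgery_type {self.surgery_type!r} is only valid for "
                f"{required_joint!r}, got joint {self.joint!r}"
            )
        if self.age <= 0:
            raise StreamValidationError(f"age must be > 0, got {self.age}")
        if self.gender not in VALID_GENDERS:
            raise StreamValidationError(f"unknown gender {self.gender!r}")
        for name in ("fjs_pre", "fjs_3m"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 100.0):
                raise StreamValidationError(f"{name} must lie in [0, 100], got {value}")

    @property
    def stratification_eligible(self) -> bool:
        """True when both FJS scores are present (pre-op and 3 months)."""
        return self.fjs_pre is not None and self.fjs_3m is not None


@dataclass(frozen=True)
class DaySummary:
    """Per patient-day derived biomarkers and QC counts.

    ``p1m``/``p6mc`` are NaN sentinels when no retained minute (respectively no
    valid 6-minute window) exists; such days are excluded downstream.
    """

    patient_id: str
    date: dt.date
    day_post_op: int
    steps: int
    p1m: float
    p6mc: float
    min_sedentary: int
    min_light: int
    min_moderate: int
    min_vigorous: int
    n_minutes_recorded: int
    n_outliers_removed: int

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise StreamValidationError("steps must be >= 0")
        parts = (
            self.min_sedentary
            + self.min_light
            + self.min_moderate
            + self.min_vigorous
        )
        if parts != self.n_minutes_recorded:
            raise StreamValidationError(
                "intensity minutes must partition retained minutes: "
                f"{parts} != {self.n_minutes_recorded}"
            )
        if not (math.isnan(self.p1m) or math.isnan(self.p6mc)):
            if self.p1m + 1e-9 < self.p6mc:
                raise StreamValidationError(
                    f"p1m ({self.p1m}) must be >= p6mc ({self.p6mc})"
                )


@dataclass
class Cohort:
    """A set of patients: metadata plus their minute streams.

    ``minutes`` is a DataFrame with columns ``patient_id, date, minute_of_day,
    steps`` (and optionally ``day_post_op``).
    """

    metadata: list[PatientMeta]
    minutes: pd.DataFrame

    def __post_init__(self) -> None:
        known = {m.patient_id for m in self.metadata}
        present = set(self.minutes["patient_id"].unique())
        orphans = present - known
        if orphans:
            raise StreamValidationError(
                f"stream records for unknown patients: {sorted(orphans)[:5]}"
            )

    @property
    def meta_by_id(self) -> dict[str, PatientMeta]:
        return {m.patient_id: m for m in self.metadata}


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StreamValidationError(f"{path}: missing columns {missing}")
    return df


def read_minute_csv(path: str | Path) -> list[MinuteRecord]:
    """Read a minute-stream CSV into validated :class:`MinuteRecord` objects.

    Rejects negative steps, non-integer or out-of-range minutes, and duplicate
    (patient, date, minute) rows, naming the offending data row (1-based,
    excluding the header).
    """
    df = validate_minute_frame(_read_csv(path, MINUTE_COLUMNS))
    return frame_to_minute_records(df)


def validate_minute_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a minute-stream DataFrame in place; returns it with parsed dates."""
    minutes = pd.to_numeric(df["minute_of_day"], errors="coerce")
    bad = minutes.isna() | (np.mod(minutes, 1) != 0)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise StreamValidationError(f"non-integer minute_of_day at data rows {rows[:10]}")
    minutes = minutes.astype(int)
    out_of_range = (minutes < 0) | (minutes > 1439)
    if out_of_range.any():
        rows = (np.flatnonzero(out_of_range.to_numpy()) + 1).tolist()
        raise StreamValidationError(f"minute_of_day out of [0, 1439] at data rows {rows[:10]}")
    steps = pd.to_numeric(df["steps"], errors="coerce")
    bad_steps = steps.isna() | (steps < 0)
    if bad_steps.any():
        rows = (np.flatnonzero(bad_steps.to_numpy()) + 1).tolist()
        raise StreamValidationError(f"negative or malformed steps at data rows {rows[:10]}")
    dup = df.duplicated(subset=["patient_id", "date", "minute_of_day"], keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 1).tolist()
        raise StreamValidationError(
            f"duplicate (patient_id, date, minute_of_day) at data rows {rows[:10]}"
        )
    df = df.copy()
    df["minute_of_day"] = minutes
    df["steps"] = steps.astype(int)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    return df


def frame_to_minute_records(df: pd.DataFrame) -> list[MinuteRecord]:
    return [
        MinuteRecord(str(r.patient_id), r.date, int(r.minute_of_day), int(r.steps))
        for r in df[MINUTE_COLUMNS].itertuples(index=False)
    ]


def minute_records_to_frame(records: Iterable[MinuteRecord]) -> pd.DataFrame:
    rows = [(r.patient_id, r.date, r.minute_of_day, r.steps) for r in records]
    return pd.DataFrame(rows, columns=MINUTE_COLUMNS)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_metadata_csv(path: str | Path) -> list[PatientMeta]:
    """Read and validate the patient metadata CSV."""
    df = _read_csv(path, METADATA_COLUMNS[:-1])  # fjs_3m may be absent entirely
    if "fjs_3m" not in df.columns:
        df = df.assign(fjs_3m=np.nan)
    df["surgery_date"] = pd.to_datetime(df["surgery_date"], format="ISO8601").dt.date
    out: list[PatientMeta] = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                PatientMeta(
                    patient_id=str(r.patient_id),
                    joint=str(r.joint),
                    surgery_type=str(r.surgery_type),
                    surgery_date=r.surgery_date,
                    age=float(r.age),
                    gender=str(r.gender),
                    bmi=float(r.bmi),
                    fjs_pre=_opt_float(r.fjs_pre),
                    fjs_3m=_opt_float(r.fjs_3m),
                )
            )
        except StreamValidationError as exc:
            raise StreamValidationError(f"metadata row {i}: {exc}") from exc
    return out


def align_to_surgery(
    minutes: pd.DataFrame | Iterable[MinuteRecord],
    metadata: Iterable[PatientMeta] | Mapping[str, PatientMeta],
) -> pd.DataFrame:
    """Annotate minute records with ``day_post_op`` (surgery day = 0).

    ``day_post_op`` is the signed whole-day difference ``date - surgery_date``,
    so the first post-operative day is 1 and pre-operative days are negative.
    """
    if not isinstance(minutes, pd.DataFrame):
        minutes = minute_records_to_frame(minutes)
    if isinstance(metadata, Mapping):
        meta_by_id = dict(metadata)
    else:
        meta_by_id = {m.patient_id: m for m in metadata}
    present = pd.unique(minutes["patient_id"])
    unknown = [p for p in present if p not in meta_by_id]
    if unknown:
        raise StreamValidationError(
            f"patients without surgery_date in metadata: {sorted(unknown)[:10]}"
        )
    surgery = minutes["patient_id"].map(
        {p: pd.Timestamp(meta_by_id[p].surgery_date) for p in present}
    )
    dates = pd.to_datetime(minutes["date"])
    out = minutes.copy()
    out["day_post_op"] = (dates - surgery).dt.days.astype(int)
    return out


def day_summaries_to_frame(summaries: Sequence[DaySummary]) -> pd.DataFrame:
    rows = [tuple(getattr(s, f.name) for f in fields(DaySummary)) for s in summaries]
    return pd.DataFrame(rows, columns=DAY_SUMMARY_COLUMNS)


def _write_with_header(df: pd.DataFrame, path: str | Path, header_meta: Mapping | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_meta:
            tags = " ".join(f"{k}={v}" for k, v in header_meta.items())
            fh.write(f"# {tags}\n")
        df.to_csv(fh, index=False)


def write_day_summaries(
    summaries: Sequence[DaySummary],
    path: str | Path,
    header_meta: Mapping | None = None,
) -> None:
    """Write day summaries as CSV in the documented column order.

    Float columns are written with Python shortest-repr formatting, so a
    read-back round-trips every value exactly.
    """
    if len(summaries) == 0:
        raise ValueError("refusing to write an empty day-summary file")
    _write_with_header(day_summaries_to_frame(summaries), path, header_meta)


def read_day_summaries(path: str | Path) -> list[DaySummary]:
    df = _read_csv(path, DAY_SUMMARY_COLUMNS)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    out = []
    for r in df[DAY_SUMMARY_COLUMNS].itertuples(index=False):
        out.append(
            DaySummary(
                patient_id=str(r.patient_id),
                date=r.date,
                day_post_op=int(r.day_post_op),
                steps=int(r.steps),
                p1m=float(r.p1m),
                p6mc=float(r.p6mc),
                min_sedentary=int(r.min_sedentary),
                min_light=int(r.min_light),
                min_moderate=int(r.min_moderate),
                min_vigorous=int(r.min_vigorous),
                n_minutes_recorded=int(r.n_minutes_recorded),
                n_outliers_removed=int(r.n_outliers_removed),
            )
        )
    return out


def write_minute_frame(
    minutes: pd.DataFrame, path: str | Path, header_meta: Mapping | None = None
) -> None:
    """Write a minute stream in the canonical four-column schema."""
    df = minutes[MINUTE_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    _write_with_header(df, path, header_meta)


def write_metadata(
    metadata: Sequence[PatientMeta], path: str | Path, header_meta: Mapping | None = None
) -> None:
    rows = []
    for m in metadata:
        rows.append(
            (
                m.patient_id,
                m.joint,
                m.surgery_type,
                m.surgery_date.isoformat(),
                m.age,
                m.gender,
                m.bmi,
                "" if m.fjs_pre is None else m.fjs_pre,
                "" if m.fjs_3m is None else m.fjs_3m,
            )
        )
    _write_with_header(pd.DataFrame(rows, columns=METADATA_COLUMNS), path, header_meta)
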