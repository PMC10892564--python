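"""Synthetic rehabilitation cohorts with known ground truth.

Generates minute-level step streams and patient metadata that emulate the
statistical structure the downstream analysis assumes:

* pre-operative days at a patient-specific baseline level, then a
  post-operative drop followed by exponential-saturation recovery
  ``level(t) = baseline * [drop + (1 + gain - drop) * (1 - exp(-t/tau))]``
  with group-specific timescales (fast vs slow recoverers);
* separate multiplicative lognormal noise channels for daily step volume and
  for cadence, so the daily-steps CV vs cadence CV contrast is directly
  controllable;
* minutes laid out as multi-minute walking bouts (geometric durations) at a
  day-level cadence, a short brisk burst that carries the single-minute peak,
  and incidental sub-20-step minutes filling the rest of the volume;
* FJS scores drawn so the MCID label matches the generating group (up to a
  configurable misclassification rate).

Every quantity the pipeline later estimates (crossing day of the recovery
curve, group slope difference) is available analytically through
:class:`SimulationTruth`.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .biomarkers import DEFAULT_THRESHOLDS, IntensityThresholds, summarize_day
from .stratification import MCID_MINUS, MCID_PLUS, mcid_threshold
from .stream_model import Cohort, PatientMeta, day_summaries_to_frame

__all__ = [
    "RecoveryCurve",
    "GeneratorParams",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_summaries",
    "truth_report",
    "timescale_for_crossing",
]

GROUPS = (MCID_PLUS, MCID_MINUS)

_BASE_SURGERY_DATE = dt.date(2023, 3, 1)


@dataclass(frozen=True)
class RecoveryCurve:
    """Relative activity level: 1.0 pre-op, exponential saturation post-op."""

    drop: float
    gain: float
    timescale: float

    def level(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.drop + (1.0 + self.gain - self.drop) * (
            1.0 - np.exp(-np.asarray(t, dtype=np.float64) / self.timescale)
        )

    def analytic_crossing(self) -> float:
        """Continuous time at which the relative level returns to 1.0 (inf if never)."""
        span = 1.0 + self.gain - self.drop
        ratio = self.gain / span
        if ratio <= 0:
            return math.inf
        return -self.timescale * math.log(ratio)

    def crossing_day(self, max_day: int) -> int | None:
        """Smallest integer day t in [1, max_day] with level(t) >= 1."""
        days = np.arange(1, max_day + 1)
        hit = np.asarray(self.level(days)) >= 1.0
        if not hit.any():
            return None
        return int(days[int(np.argmax(hit))])


def timescale_for_crossing(drop: float, gain: float, day: int) -> float:
    """Timescale making the continuous crossing fall at ``day - 0.5``.

    The integer crossing day of the resulting curve is exactly ``day``.
    """
    span = 1.0 + gain - drop
    denom = -math.log(gain / span)
    return (day - 0.5) / denom


@dataclass
class GeneratorParams:
    """Everything the generator needs; all rates/fractions validated."""

    n_per_group: int = 20  # patients per (joint x recovery-group) cell
    joints: tuple[str, ...] = ("hip",)
    preop_days: int = 14
    postop_days: int = 60
    preop_mean_steps: float = 4477.0
    preop_p1m_target: float = 92.0
    preop_p6mc_target: float = 61.0
    postop_drop: float = 0.3
    recovery_timescale: dict[str, float] = field(
        default_factory=lambda: {MCID_PLUS: 16.0, MCID_MINUS: 26.0}
    )
    plateau_gain: dict[str, float] = field(
        default_factory=lambda: {MCID_PLUS: 0.12, MCID_MINUS: 0.05}
    )
    steps_noise_cv: float = 0.8
    cadence_noise_cv: float = 0.4
    between_patient_cv: float = 0.35
    between_patient_cadence_cv: float = 0.12
    bout_duration_mean: float = 10.0
    cadence_sd_within_bout: float = 6.0
    walk_share: float = 0.55  # fraction of daily steps accumulated in bouts
    incidental_mean: float = 7.0
    wake_start: int = 420
    wake_end: int = 1380
    nonwear_dropout: float = 0.0  # probability a whole day is missing
    outlier_rate: float = 0.0  # expected injected >cutoff minutes per day
    age_mean: float = 62.0
    age_sd: float = 10.0
    female_fraction: float = 0.51
    fjs_delta_mean: dict[str, float] = field(
        default_factory=lambda: {MCID_PLUS: 28.0, MCID_MINUS: 7.0}
    )
    fjs_delta_sd: float = 5.0
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not set(self.joints) <= {"hip", "knee"}:
            raise ValueError(f"unknown joints {self.joints}")
        if not (0.0 < self.postop_drop < 1.0):
            raise ValueError("postop_drop must lie in (0, 1)")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must lie in [0, 1]")
        for name in (
            "preop_mean_steps",
            "preop_p1m_target",
            "preop_p6mc_target",
            "steps_noise_cv",
            "cadence_noise_cv",
            "bout_duration_mean",
            "cadence_sd_within_bout",
            "walk_share",
            "incidental_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for g in GROUPS:
            if self.recovery_timescale.get(g, 0) <= 0:
                raise ValueError(f"recovery_timescale missing/invalid for {g}")
            if self.plateau_gain.get(g, -1) < 0:
                raise ValueError(f"plateau_gain missing/invalid for {g}")
        if not (0 <= self.wake_start < self.wake_end <= 1440):
            raise ValueError("wake window must satisfy 0 <= start < end <= 1440")
        if not (0.0 <= self.nonwear_dropout < 1.0):
            raise ValueError("nonwear_dropout must lie in [0, 1)")
        if not (0.0 <= self.misclassification_rate <= 1.0):
            raise ValueError("misclassification_rate must lie in [0, 1]")

    def curve(self, group: str) -> RecoveryCurve:
        return RecoveryCurve(
            drop=self.postop_drop,
            gain=self.plateau_gain[group],
            timescale=self.recovery_timescale[group],
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Known generating parameters, derived deterministically from the params."""

    curves: dict[str, RecoveryCurve]
    crossing_day: dict[str, int | None]
    analytic_crossing: dict[str, float]
    slope_difference: dict[str, float]  # mean derivative gap (plus - minus), per outcome
    day_range: tuple[int, int]


def truth_report(params: GeneratorParams) -> SimulationTruth:
    """Analytic ground truth implied by the generator parameters."""
    curves = {g: params.curve(g) for g in GROUPS}
    t_lo, t_hi = 1, params.postop_days
    crossing = {g: c.crossing_day(t_hi) for g, c in curves.items()}
    analytic = {g: c.analytic_crossing() for g, c in curves.items()}
    # mean derivative of level over [t_lo, t_hi] == (level(hi) - level(lo)) / (hi - lo)
    if t_hi > t_lo:
        rel_gap = (
            (curves[MCID_PLUS].level(t_hi) - curves[MCID_PLUS].level(t_lo))
            - (curves[MCID_MINUS].level(t_hi) - curves[MCID_MINUS].level(t_lo))
        ) / (t_hi - t_lo)
    else:
        rel_gap = 0.0
    scale = {
        "steps": params.preop_mean_steps,
        "p1m": params.preop_p1m_target,
        "p6mc": params.preop_p6mc_target,
    }
    slope_diff = {k: float(rel_gap * v) for k, v in scale.items()}
    return SimulationTruth(
        curves=curves,
        crossing_day=crossing,
        analytic_crossing=analytic,
        slope_difference=slope_diff,
        day_range=(t_lo, t_hi),
    )


@dataclass
class _Patient:
    meta: PatientMeta
    group: str
    level_steps: float
    level_p1m: float
    level_p6mc: float


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with median 1 and the given CV.

    Median-preserving (mu = 0) so that cohort medians land on the calibration
    targets; the mean is inflated by exp(sigma^2 / 2), identically pre- and
    post-op, so recovery-curve crossings are unaffected.
    """
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _draw_patient(
    rng: np.random.Generator, params: GeneratorParams, idx: int, joint: str, group: str
) -> _Patient:
    pid = f"P{idx:04d}"
    surgery_date = _BASE_SURGERY_DATE + dt.timedelta(days=idx % 28)
    age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 40.0, 90.0))
    gender = "female" if rng.random() < params.female_fraction else "male"
    bmi = float(np.clip(rng.normal(29.0, 4.0), 18.0, 45.0))
    threshold = mcid_threshold(joint, "total")
    fjs_pre = float(np.clip(rng.normal(12.0, 6.0), 0.0, 40.0))
    delta = rng.normal(params.fjs_delta_mean[group], params.fjs_delta_sd)
    want_plus = group == MCID_PLUS
    achieved = delta >= threshold
    if achieved != want_plus:
        delta = 2.0 * threshold - delta  # reflect to the intended side
        if not want_plus and delta >= threshold:
            delta = threshold - 0.1
    if rng.random() < params.misclassification_rate:
        delta = 2.0 * threshold - delta
        if want_plus and delta >= threshold:
            delta = threshold - 0.1
    fjs_3m = float(np.clip(fjs_pre + delta, 0.0, 100.0))
    meta = PatientMeta(
        patient_id=pid,
        joint=joint,
        surgery_type="total",
        surgery_date=surgery_date,
        age=round(age, 1),
        gender=gender,
        bmi=round(bmi, 1),
        fjs_pre=round(fjs_pre, 1),
        fjs_3m=round(fjs_3m, 1),
    )
    level_steps = params.preop_mean_steps * _lognormal_factor(rng, params.between_patient_cv)
    cadence_fac = _lognormal_factor(rng, params.between_patient_cadence_cv)
    return _Patient(
        meta=meta,
        group=group,
        level_steps=float(level_steps),
        level_p1m=float(params.preop_p1m_target * cadence_fac),
        level_p6mc=float(params.preop_p6mc_target * cadence_fac),
    )


def _simulate_day(
    rng: np.random.Generator,
    params: GeneratorParams,
    steps_target: float,
    c6: float,
    c1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Lay one day's activity out on the minute grid.

    Returns parallel (minute_of_day, steps) arrays sorted by minute.
    """
    cutoff = DEFAULT_THRESHOLDS.outlier_cutoff
    window = params.wake_end - params.wake_start
    c6 = float(np.clip(c6, 8.0, cutoff - 10.0))
    c1 = float(np.clip(c1, c6 + 4.0, cutoff - 1.0))

    walk_minutes = int(round(steps_target * params.walk_share / c6))
    walk_minutes = max(0, min(walk_minutes, int(0.5 * window)))
    durations: list[int] = []
    p = 1.0 / params.bout_duration_mean
    remaining = walk_minutes
    while remaining > 0:
        d = int(min(rng.geometric(p), remaining))
        durations.append(d)
        remaining -= d

    bout_vals = np.clip(
        np.rint(rng.normal(c6, params.cadence_sd_within_bout, walk_minutes)), 1, cutoff
    ).astype(np.int64)
    # short brisk burst carrying the single-minute peak
    burst = np.clip(np.rint(rng.normal(c1, 3.0, 2)), 1, cutoff).astype(np.int64)

    walking_steps = int(bout_vals.sum()) + int(burst.sum())
    residual = max(steps_target - walking_steps, 0.0)
    avail = window - walk_minutes - 2 - 8
    n_incidental = int(round(residual / params.incidental_mean))
    n_incidental = max(0, min(n_incidental, avail))
    if n_incidental:
        # adapt the per-minute mean so a capped count still hits the volume
        eff_mean = float(np.clip(residual / n_incidental, 1.0, 18.0))
        inc = np.clip(
            1 + rng.poisson(max(eff_mean - 1.0, 0.0), n_incidental), 1, 19
        ).astype(np.int64)
    else:
        inc = np.empty(0, dtype=np.int64)

    n_outlier = int(rng.poisson(params.outlier_rate)) if params.outlier_rate > 0 else 0
    out_vals = (
        rng.integers(int(cutoff) + 1, int(cutoff) + 80, n_outlier).astype(np.int64)
        if n_outlier
        else np.empty(0, dtype=np.int64)
    )

    values = np.concatenate([bout_vals, burst, inc, out_vals])
    lengths = np.concatenate(
        [
            np.asarray(durations, dtype=np.int64),
            np.array([2], dtype=np.int64),
            np.ones(n_incidental + n_outlier, dtype=np.int64),
        ]
    )
    n_blocks = len(lengths)
    total = int(lengths.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)

    perm = rng.permutation(n_blocks)
    src_start = np.concatenate([[0], np.cumsum(lengths[:-1])])[perm]
    lengths_p = lengths[perm]
    within = np.arange(total) - np.repeat(np.cumsum(lengths_p) - lengths_p, lengths_p)
    steps = values[np.repeat(src_start, lengths_p) + within]

    free = window - total
    gaps = rng.multinomial(free, np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
    starts = params.wake_start + np.cumsum(gaps[:-1]) + np.concatenate(
        [[0], np.cumsum(lengths_p[:-1])]
    )
    minutes = np.repeat(starts, lengths_p) + within
    return minutes.astype(np.int64), steps


def _generate(
    params: GeneratorParams,
) -> Iterator[tuple[_Patient, list[tuple[int, dt.date, np.ndarray, np.ndarray]]]]:
    """Yield each patient with their per-day minute arrays (deterministic order)."""
    rng = np.random.default_rng(params.seed)
    idx = 0
    for joint in params.joints:
        for group in GROUPS:
            curve = params.curve(group)
            for _ in range(params.n_per_group):
                patient = _draw_patient(rng, params, idx, joint, group)
                idx += 1
                days: list[tuple[int, dt.date, np.ndarray, np.ndarray]] = []
                for d in range(-params.preop_days, params.postop_days + 1):
                    if d == 0:
                        continue  # surgery day itself is not monitored
                    if params.nonwear_dropout > 0 and rng.random() < params.nonwear_dropout:
                        continue
                    rel = 1.0 if d < 0 else float(curve.level(d))
                    s_noise = _lognormal_factor(rng, params.steps_noise_cv)
                    c_noise = _lognormal_factor(rng, params.cadence_noise_cv)
                    steps_target = patient.level_steps * rel * s_noise
                    c6 = patient.level_p6mc * rel * c_noise
                    c1 = patient.level_p1m * rel * c_noise
                    mins, steps = _simulate_day(rng, params, steps_target, c6, c1)
                    if mins.size == 0:
                        continue
                    date = patient.meta.surgery_date + dt.timedelta(days=d)
                    days.append((d, date, mins, steps))
                yield patient, days


def simulate_cohort(params: GeneratorParams) -> tuple[Cohort, SimulationTruth]:
    """Generate a full cohort: metadata plus one minute frame for all patients.

    Reproducible: the same params (including seed) give identical output.
    The returned minute frame carries ``day_post_op`` alongside the canonical
    minute-stream columns.
    """
    truth = truth_report(params)
    metas: list[PatientMeta] = []
    pid_chunks: list[np.ndarray] = []
    date_chunks: list[np.ndarray] = []
    minute_chunks: list[np.ndarray] = []
    step_chunks: list[np.ndarray] = []
    dpo_chunks: list[np.ndarray] = []
    for patient, days in _generate(params):
        metas.append(patient.meta)
        for d, date, mins, steps in days:
            n = mins.size
            pid_chunks.append(np.full(n, patient.meta.patient_id, dtype=object))
            date_chunks.append(np.full(n, date, dtype=object))
            minute_chunks.append(mins)
            step_chunks.append(steps)
            dpo_chunks.append(np.full(n, d, dtype=np.int64))
    if not minute_chunks:
        raise ValueError("generator produced no data (check dropout/params)")
    minutes = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_chunks),
            "date": np.concatenate(date_chunks),
            "minute_of_day": np.concatenate(minute_chunks),
            "steps": np.concatenate(step_chunks),
            "day_post_op": np.concatenate(dpo_chunks),
        }
    )
    return Cohort(metadata=metas, minutes=minutes), truth


def simulate_summaries(
    params: GeneratorParams,
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, list[PatientMeta], SimulationTruth]:
    """Generate a cohort and run the per-day biomarker pipeline immediately.

    Equivalent to ``summarize_cohort(simulate_cohort(...))`` (same random
    stream, same biomarker code path) but without materializing the cohort
    minute frame — the fast route for large simulation studies.
    """
    truth = truth_report(params)
    metas: list[PatientMeta] = []
    summaries = []
    for patient, days in _generate(params):
        metas.append(patient.meta)
        for d, date, mins, steps in days:
            summaries.append(
                summarize_day(patient.meta.patient_id, date, d, (mins, steps), thresholds)
            )
    if not summaries:
        raise ValueError("generator produced no data (check dropout/params)")
    return day_summaries_to_frame(summaries), metas, truth
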