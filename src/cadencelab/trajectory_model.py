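"""Random-intercept recovery-trajectory modelling.

Fits, by maximum likelihood, the linear mixed model

    outcome[i, t] = alpha + b1*day + b2*group + b3*(day x group)
                    + b4*age_centered + b5*gender + a_i + eps[i, t]

with one random intercept ``a_i ~ N(0, mu2)`` per patient and independent
residuals ``eps ~ N(0, sigma2)``, after per-group baseline normalization
(each group's first-session mean is subtracted from all of that group's
values).  From the fit it derives

* ``time_to_preop_return`` — the earliest integer day at which a group's
  predicted trajectory (back on the un-normalized scale) reaches the group's
  pre-operative reference level, with a parametric-bootstrap 95% CI;
* ``group_separation_day`` — the earliest integer day at which the Wald 95%
  CI of the group contrast ``b2 + b3*t`` excludes zero.

The group factor enters as a 0/1 indicator (reference group coded 0); age is
centered at its sample mean and gender is a male indicator (female reference),
so the intercept refers to the reference group at the mean age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ReturnDayEstimate",
    "SeparationEstimate",
    "PreopReference",
    "ConvergenceError",
    "normalize_baseline",
    "fit_mixed_model",
    "residual_diagnostics",
    "preop_reference",
    "predict_group_trajectory",
    "time_to_preop_return",
    "group_separation_day",
]

NOT_REACHED = None  # sentinel for "trajectory never crosses within the day range"

TERM_INTERCEPT = "intercept"
TERM_DAY = "day"
TERM_GROUP = "group"
TERM_INTERACTION = "day:group"
TERM_AGE = "age"
TERM_GENDER = "gender"


class ConvergenceError(RuntimeError):
    """Raised when the mixed-model optimizer fails to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """What to model: outcome column, grouping factor and day range."""

    outcome: str = "steps"
    group_factor: str = "recovery_label"
    day_range: tuple[int, int] = (1, 60)
    covariates: tuple[str, ...] = ("age", "gender")

    def __post_init__(self) -> None:
        lo, hi = self.day_range
        if lo < 1 or hi < lo:
            raise ValueError(f"day_range lower bound must be >= 1, got {self.day_range}")
        unknown = set(self.covariates) - {"age", "gender"}
        if unknown:
            raise ValueError(f"unsupported covariates {sorted(unknown)}")


@dataclass
class ModelFit:
    """Maximum-likelihood estimates of the random-intercept model."""

    params: dict[str, float]
    vcov: pd.DataFrame  # covariance of the fixed-effect estimates
    sigma2: float  # residual variance
    mu2: float  # random-intercept variance
    loglik: float
    converged: bool
    n_obs: int
    n_patients: int
    covariate_means: dict[str, float] = field(default_factory=dict)
    resid: np.ndarray | None = None
    fitted: np.ndarray | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.params)

    def beta(self, term: str) -> float:
        return self.params.get(term, 0.0)

    def se(self, term: str) -> float:
        return float(np.sqrt(self.vcov.loc[term, term]))


@dataclass(frozen=True)
class ReturnDayEstimate:
    group: str
    day: int | None  # None == not reached within the day range
    ci_low: int | None
    ci_high: int | None
    preop_mean: float

    @property
    def reached(self) -> bool:
        return self.day is not None


@dataclass(frozen=True)
class SeparationEstimate:
    day: int | None
    ci_low: int | None
    ci_high: int | None

    @property
    def reached(self) -> bool:
        return self.day is not None


@dataclass(frozen=True)
class PreopReference:
    """Group mean of per-patient pre-operative means, with a t-based 95% CI."""

    group: str
    mean: float
    ci_low: float
    ci_high: float
    n_patients: int


def normalize_baseline(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    day_col: str = "day",
    first_day: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Subtract each group's first-session mean from all of its values.

    The first session is ``first_day`` when given, otherwise each group's
    earliest observed day.  Returns the normalized frame (value column
    replaced) and the per-group offsets that were subtracted; after the
    operation every group's first-session mean is exactly 0.
    """
    if data.empty:
        raise ValueError("cannot normalize an empty table")
    out = data.copy()
    out[value_col] = out[value_col].astype(np.float64)
    offsets: dict = {}
    for group, grp in data.groupby(group_col, sort=True):
        day0 = first_day if first_day is not None else int(grp[day_col].min())
        first = grp.loc[grp[day_col] == day0, value_col]
        if first.empty:
            raise ValueError(f"group {group!r} has no data at first session day {day0}")
        offsets[group] = float(first.mean())
        out.loc[grp.index, value_col] = grp[value_col] - offsets[group]
    return out, offsets


def _design(
    data: pd.DataFrame,
    spec: ModelSpec,
    value_col: str,
    day_col: str,
    group_col: str,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, dict[str, float]]:
    endog = data[value_col].to_numpy(dtype=np.float64)
    cols: dict[str, np.ndarray] = {
        TERM_INTERCEPT: np.ones(len(data)),
        TERM_DAY: data[day_col].to_numpy(dtype=np.float64),
    }
    group = data[group_col].to_numpy(dtype=np.float64)
    if len(np.unique(group)) > 1:  # constant group would be rank-deficient
        cols[TERM_GROUP] = group
        cols[TERM_INTERACTION] = cols[TERM_DAY] * group
    means: dict[str, float] = {}
    if "age" in spec.covariates and "age" in data.columns:
        age = data["age"].to_numpy(dtype=np.float64)
        means["age"] = float(age.mean())
        cols[TERM_AGE] = age - means["age"]
    if "gender" in spec.covariates and "gender" in data.columns:
        g = data["gender"]
        male = (
            (g == "male").to_numpy(dtype=np.float64)
            if g.dtype == object
            else g.to_numpy(dtype=np.float64)
        )
        means["gender"] = float(male.mean())
        cols[TERM_GENDER] = male
    exog = pd.DataFrame(cols)
    groups = data["patient_id"].to_numpy()
    return endog, exog, groups, means


def fit_mixed_model(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    value_col: str = "value",
    day_col: str = "day",
    group_col: str = "group",
) -> ModelFit:
    """ML fit of the random-intercept model to a normalized outcome table.

    ``data`` needs columns ``patient_id``, ``day``, the outcome value, and a
    0/1 group indicator; ``age``/``gender`` columns are used when the spec
    requests them.  Repeated measures share one random intercept per patient.

    Raises :class:`ConvergenceError` when the optimizer does not converge; a
    singular fit (``mu2 -> 0``) is returned with a warning.
    """
    spec = spec or ModelSpec()
    lo, hi = spec.day_range
    data = data[(data[day_col] >= lo) & (data[day_col] <= hi)]
    data = data[np.isfinite(data[value_col].to_numpy(dtype=np.float64))]
    if data.empty:
        raise ValueError("no observations inside the model day range")
    sizes = data.groupby(group_col)["patient_id"].nunique()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"need >= 2 patients per group, offending groups: {small}")

    endog, exog, groups, means = _design(data, spec, value_col, day_col, group_col)
    model = MixedLM(endog, exog, groups=groups)
    result = None
    attempts: list[str] = []
    # lbfgs is fast on well-behaved data; powell/nm are derivative-free and
    # handle the mu2 -> 0 boundary where the hessian turns singular
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                candidate = model.fit(reml=False, method=method, maxiter=2000, disp=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            attempts.append(f"{method}: {exc}")
            continue
        # optimizers can claim convergence while returning a degenerate fit
        # (infinite likelihood, non-finite covariance) at the mu2 -> 0 boundary
        ok = (
            candidate.converged
            and np.isfinite(candidate.llf)
            and np.all(np.isfinite(np.asarray(candidate.fe_params)))
            and np.all(np.isfinite(np.asarray(candidate.cov_params())))
        )
        if ok:
            result = candidate
            break
        attempts.append(f"{method}: not converged or degenerate")
    if result is None:
        raise ConvergenceError(
            "mixed-model optimizer did not converge "
            f"(n_obs={len(endog)}, n_patients={len(np.unique(groups))}; "
            f"attempts: {'; '.join(attempts)})"
        )
    k_fe = exog.shape[1]
    fe = np.asarray(result.fe_params, dtype=np.float64)
    vcov_fe = np.asarray(result.cov_params())[:k_fe, :k_fe]
    mu2 = float(np.atleast_2d(np.asarray(result.cov_re))[0, 0])
    if mu2 < 1e-10 * max(float(result.scale), 1.0):
        warnings.warn("singular fit: random-intercept variance is ~0", RuntimeWarning)
    names = list(exog.columns)
    # marginal fitted values (fixed effects only); robust to singular cov_re
    fitted = exog.to_numpy(dtype=np.float64) @ fe
    return ModelFit(
        params=dict(zip(names, fe)),
        vcov=pd.DataFrame(vcov_fe, index=names, columns=names),
        sigma2=float(result.scale),
        mu2=mu2,
        loglik=float(result.llf),
        converged=bool(result.converged),
        n_obs=len(endog),
        n_patients=int(len(np.unique(groups))),
        covariate_means=means,
        resid=endog - fitted,
        fitted=fitted,
    )


@dataclass(frozen=True)
class Diagnostics:
    resid: np.ndarray
    fitted: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    resid_fitted_slope: float
    resid_fitted_slope_se: float
    qq_deviation: float  # max |sample - theoretical| on standardized residuals


def residual_diagnostics(fit: ModelFit) -> Diagnostics:
    """Residual-vs-fitted slope and normal-quantile pairs for a fitted model."""
    if fit.resid is None or fit.fitted is None:
        raise ValueError("fit carries no residuals")
    resid, fitted = fit.resid, fit.fitted
    n = len(resid)
    (qq_theo, qq_samp), _ = stats.probplot(resid, dist="norm")
    spread = fitted - fitted.mean()
    denom = float(spread @ spread)
    if denom > 0:
        slope = float(spread @ resid / denom)
        dof = max(n - 2, 1)
        resid_perp = resid - slope * spread
        s2 = float(resid_perp @ resid_perp) / dof
        slope_se = float(np.sqrt(s2 / denom))
    else:
        slope, slope_se = 0.0, float("inf")
    sd = resid.std(ddof=1) if n > 1 else 1.0
    std_sorted = np.sort(resid) / (sd if sd > 0 else 1.0)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq_dev = float(np.max(np.abs(std_sorted - theo))) if n else 0.0
    return Diagnostics(
        resid=resid,
        fitted=fitted,
        qq_theoretical=np.asarray(qq_theo),
        qq_sample=np.asarray(qq_samp),
        resid_fitted_slope=slope,
        resid_fitted_slope_se=slope_se,
        qq_deviation=qq_dev,
    )


def preop_reference(
    day_summaries: pd.DataFrame,
    outcome: str,
    group_of: Mapping[str, str],
    conf_level: float = 0.95,
) -> dict[str, PreopReference]:
    """Per-group pre-operative reference level.

    Each patient contributes the mean of their pre-operative (day_post_op < 0)
    daily values; the group reference is the mean of those per-patient means
    with a t-based CI (equal patient weighting).
    """
    pre = day_summaries[day_summaries["day_post_op"] < 0]
    pre = pre[np.isfinite(pre[outcome].to_numpy(dtype=np.float64))]
    if pre.empty:
        raise ValueError("no pre-operative day summaries available")
    per_patient = pre.groupby("patient_id")[outcome].mean()
    out: dict[str, PreopReference] = {}
    groups = pd.Series({p: group_of.get(p) for p in per_patient.index})
    for group, vals in per_patient.groupby(groups):
        if group is None:
            continue
        arr = vals.to_numpy(dtype=np.float64)
        mean = float(arr.mean())
        if arr.size > 1:
            half = stats.t.ppf(0.5 + conf_level / 2, arr.size - 1) * arr.std(ddof=1) / np.sqrt(arr.size)
        else:
            half = float("nan")
        out[str(group)] = PreopReference(
            group=str(group),
            mean=mean,
            ci_low=mean - half,
            ci_high=mean + half,
            n_patients=int(arr.size),
        )
    return out


def _term_index(fit: ModelFit) -> dict[str, int]:
    return {name: i for i, name in enumerate(fit.terms)}


def _trajectory_from_beta(
    beta: np.ndarray, idx: Mapping[str, int], days: np.ndarray, group_value: float,
    covariate_means: Mapping[str, float],
) -> np.ndarray:
    """Predicted normalized outcome at mean covariates; beta may be 2-D (draws x terms)."""
    beta = np.atleast_2d(beta)
    pred = beta[:, idx[TERM_INTERCEPT], None] + np.outer(beta[:, idx[TERM_DAY]], days)
    if TERM_GROUP in idx:
        pred += beta[:, idx[TERM_GROUP], None] * group_value
        pred += np.outer(beta[:, idx[TERM_INTERACTION]], days) * group_value
    if TERM_AGE in idx:
        pred += 0.0  # age is centered: mean-age prediction
    if TERM_GENDER in idx:
        pred += beta[:, idx[TERM_GENDER], None] * covariate_means.get("gender", 0.0)
    return pred


def predict_group_trajectory(
    fit: ModelFit, group_value: float, days: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Point prediction of the normalized outcome for one group at mean covariates."""
    days = np.asarray(days, dtype=np.float64)
    beta = np.array([fit.params[t] for t in fit.terms])
    return _trajectory_from_beta(beta, _term_index(fit), days, group_value, fit.covariate_means)[0]


def _first_crossing(pred: np.ndarray, days: np.ndarray, target: float) -> float:
    """Smallest day with pred >= target; +inf when never (vectorized helper)."""
    hit = pred >= target
    if not hit.any():
        return np.inf
    return float(days[int(np.argmax(hit))])


def time_to_preop_return(
    fit: ModelFit,
    group: str,
    group_value: float,
    baseline_offset: float,
    preop: PreopReference,
    day_range: tuple[int, int],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> ReturnDayEstimate:
    """Earliest integer day at which the group trajectory reaches pre-op level.

    The fitted (normalized-scale) trajectory is shifted back by the group's
    baseline offset and compared with the pre-operative reference mean.  The
    95% CI comes from a parametric bootstrap over the fixed-effect estimates
    (draws from a normal with the fitted covariance).
    """
    rng = rng or np.random.default_rng(0)
    lo, hi = day_range
    days = np.arange(lo, hi + 1, dtype=np.float64)
    idx = _term_index(fit)
    beta_hat = np.array([fit.params[t] for t in fit.terms])
    target = preop.mean - baseline_offset  # on the normalized scale

    point_pred = _trajectory_from_beta(beta_hat, idx, days, group_value, fit.covariate_means)[0]
    day = _first_crossing(point_pred, days, target)

    cov = fit.vcov.to_numpy()
    draws = rng.multivariate_normal(beta_hat, cov, size=n_boot, method="cholesky")
    preds = _trajectory_from_beta(draws, idx, days, group_value, fit.covariate_means)
    hit = preds >= target
    any_hit = hit.any(axis=1)
    not_reached = hi + 1.0  # ranks "never crossed" beyond every real day
    crossing = np.where(any_hit, days[np.argmax(hit, axis=1)], not_reached)
    ci_low, ci_high = np.percentile(crossing, [2.5, 97.5])

    def _as_day(x: float) -> int | None:
        return None if x > hi else int(round(x))

    return ReturnDayEstimate(
        group=group,
        day=_as_day(day),
        ci_low=_as_day(ci_low),
        ci_high=_as_day(ci_high),
        preop_mean=preop.mean,
    )


def separation_scan(
    beta2: float,
    beta3: float,
    v22: float,
    v23: float,
    v33: float,
    day_range: tuple[int, int],
    z: float,
) -> int | None:
    """Smallest integer day with |beta2 + beta3*t| > z * se(t); None if never."""
    lo, hi = day_range
    days = np.arange(lo, hi + 1, dtype=np.float64)
    contrast = beta2 + beta3 * days
    var = v22 + 2.0 * days * v23 + days * days * v33
    se = np.sqrt(np.maximum(var, 0.0))
    hit = np.abs(contrast) > z * se
    if not hit.any():
        return None
    return int(days[int(np.argmax(hit))])


def group_separation_day(
    fit: ModelFit,
    day_range: tuple[int, int],
    alpha: float = 0.05,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> SeparationEstimate:
    """Earliest integer day at which the group contrast is significant.

    The contrast ``b2 + b3*t`` is tested with a Wald interval from the
    fixed-effect covariance; the returned day is the smallest t in the range
    whose interval excludes 0.  A bootstrap over (b2, b3) draws (plug-in
    covariance) yields a 95% CI on the day itself.
    """
    if TERM_GROUP not in fit.params or TERM_INTERACTION not in fit.params:
        raise ValueError("fit lacks group main effect / interaction terms")
    z = float(stats.norm.ppf(1 - alpha / 2))
    b2, b3 = fit.params[TERM_GROUP], fit.params[TERM_INTERACTION]
    v22 = float(fit.vcov.loc[TERM_GROUP, TERM_GROUP])
    v23 = float(fit.vcov.loc[TERM_GROUP, TERM_INTERACTION])
    v33 = float(fit.vcov.loc[TERM_INTERACTION, TERM_INTERACTION])
    day = separation_scan(b2, b3, v22, v23, v33, day_range, z)

    rng = rng or np.random.default_rng(0)
    cov = np.array([[v22, v23], [v23, v33]])
    draws = rng.multivariate_normal([b2, b3], cov, size=n_boot, method="cholesky")
    lo, hi = day_range
    days = np.arange(lo, hi + 1, dtype=np.float64)
    contrast = draws[:, [0]] + draws[:, [1]] * days
    var = v22 + 2.0 * days * v23 + days * days * v33
    hit = np.abs(contrast) > z * np.sqrt(np.maximum(var, 0.0))
    any_hit = hit.any(axis=1)
    not_reached = hi + 1.0
    crossing = np.where(any_hit, days[np.argmax(hit, axis=1)], not_reached)
    ci_low, ci_high = np.percentile(crossing, [2.5, 97.5])

    def _as_day(x) -> int | None:
        return None if x > hi else int(round(x))

    return SeparationEstimate(day=day, ci_low=_as_day(ci_low), ci_high=_as_day(ci_high))
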