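"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force
enumeration for the sliding-window cadence peak, a direct multivariate-normal
density for the mixed-model likelihood, and interval analysis of the Wald
quadratic for the separation day.
"""

import math

import numpy as np
from scipy.stats import multivariate_normal


def brute_force_p6mc(minutes_steps: dict[int, int], removed: set[int], window: int = 6):
    """Enumerate every window start over the recorded span."""
    all_minutes = set(minutes_steps) | set(removed)
    if not all_minutes:
        return float("nan")
    lo, hi = min(all_minutes), max(all_minutes)
    best = None
    for j in range(lo, hi - window + 2):
        win = range(j, j + window)
        if any(m in removed for m in win):
            continue
        mean = sum(minutes_steps.get(m, 0) for m in win) / window
        best = mean if best is None else max(best, mean)
    return float("nan") if best is None else best


def direct_loglik(df, beta, sigma2, mu2, exog_cols):
    """Marginal MVN log-density of a random-intercept model, per-patient blocks."""
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in exog_cols])
    mean = X @ beta
    ll = 0.0
    for pid in df.patient_id.unique():
        m = (df.patient_id == pid).to_numpy()
        n = int(m.sum())
        cov = sigma2 * np.eye(n) + mu2 * np.ones((n, n))
        ll += multivariate_normal.logpdf(df.value[m], mean[m], cov)
    return ll


def closed_form_separation(b2, b3, v22, v23, v33, day_range, z):
    """Analytic separation day.

    |b2 + b3 t| > z se(t) is the quadratic
    q(t) = (b3^2 - z^2 v33) t^2 + 2 (b2 b3 - z^2 v23) t + (b2^2 - z^2 v22) > 0.
    The solution set is derived from the roots (no scanning); the result is
    the smallest integer of [lo, hi] inside it.
    """
    a = b3 * b3 - z * z * v33
    b = 2.0 * (b2 * b3 - z * z * v23)
    c = b2 * b2 - z * z * v22
    lo, hi = day_range

    def smallest_integer_in(intervals):
        for s, e in intervals:  # open intervals (s, e)
            t = lo if s == -math.inf else max(lo, math.floor(s) + 1)
            while t <= s:  # guard float edge: need t strictly > s
                t += 1
            if t <= hi and t < e:
                return t
        return None

    if a == 0.0:
        if b == 0.0:
            intervals = [(-math.inf, math.inf)] if c > 0 else []
        elif b > 0:
            intervals = [(-c / b, math.inf)]
        else:
            intervals = [(-math.inf, -c / b)]
        return smallest_integer_in(intervals)

    disc = b * b - 4.0 * a * c
    if disc <= 0:
        intervals = [(-math.inf, math.inf)] if a > 0 else []
        return smallest_integer_in(intervals)
    r = math.sqrt(disc)
    r1, r2 = sorted(((-b - r) / (2 * a), (-b + r) / (2 * a)))
    if a > 0:
        # solution set (-inf, r1) U (r2, inf); lo is eligible iff lo < r1
        if lo < r1:
            return lo
        return smallest_integer_in([(r2, math.inf)])
    return smallest_integer_in([(r1, r2)])
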