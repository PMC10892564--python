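import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from oracles import closed_form_separation, direct_loglik

from cadencelab.trajectory_model import (
    ModelFit,
    ModelSpec,
    PreopReference,
    fit_mixed_model,
    group_separation_day,
    normalize_baseline,
    preop_reference,
    predict_group_trajectory,
    residual_diagnostics,
    separation_scan,
    time_to_preop_return,
)

SPEC_NO_COV = ModelSpec(day_range=(1, 60), covariates=())


def lmm_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "day", "value", "group"])


def make_fit(b):
    """Construct a ModelFit by hand from {term: (beta, var)}."""
    names = list(b)
    params = {k: v[0] for k, v in b.items()}
    vcov = pd.DataFrame(np.diag([v[1] for v in b.values()]), index=names, columns=names)
    return ModelFit(
        params=params,
        vcov=vcov,
        sigma2=1.0,
        mu2=0.0,
        loglik=0.0,
        converged=True,
        n_obs=0,
        n_patients=0,
    )


# --- normalize_baseline ----------------------------------------------------


class TestNormalizeBaseline:
    def test_hand_arithmetic(self):
        df = lmm_frame([("a", 1, 10.0, 0), ("b", 1, 20.0, 0), ("a", 2, 25.0, 0)])
        out, offsets = normalize_baseline(df)
        assert offsets[0] == 15.0
        assert out["value"].tolist() == [-5.0, 5.0, 10.0]

    def test_constant_data_all_zero(self):
        df = lmm_frame([("a", d, 7.0, 0) for d in range(1, 5)])
        out, _ = normalize_baseline(df)
        assert out["value"].tolist() == [0.0] * 4

    def test_two_groups_both_start_at_zero(self):
        df = lmm_frame(
            [("a", 1, 10.0, 0), ("b", 1, 30.0, 1), ("a", 2, 12.0, 0), ("b", 2, 33.0, 1)]
        )
        out, offsets = normalize_baseline(df)
        for g in (0, 1):
            first = out[(out.group == g) & (out.day == 1)]["value"]
            assert first.mean() == 0.0
        assert offsets == {0: 10.0, 1: 30.0}

    def test_missing_first_session_errors(self):
        df = lmm_frame([("a", 1, 10.0, 0), ("b", 5, 30.0, 1)])
        with pytest.raises(ValueError, match="1"):
            normalize_baseline(df, first_day=1)


# --- fit_mixed_model -------------------------------------------------------


def exact_linear_frame(n_per_group=3, days=4, beta=(1.0, 0.5, 2.0, 0.3)):
    a, b1, b2, b3 = beta
    rows = []
    for i in range(2 * n_per_group):
        g = float(i >= n_per_group)
        for t in range(1, days + 1):
            rows.append((f"p{i}", t, a + b1 * t + b2 * g + b3 * t * g, g))
    return lmm_frame(rows)


class TestFitMixedModel:
    def test_noiseless_identifiability(self):
        df = exact_linear_frame()
        fit = fit_mixed_model(df, SPEC_NO_COV)
        for term, truth in zip(("intercept", "day", "group", "day:group"), (1.0, 0.5, 2.0, 0.3)):
            assert fit.params[term] == pytest.approx(truth, rel=1e-6, abs=1e-9)

    def test_loglik_matches_direct_density_oracle(self):
        # 3 patients x 4 days, one group (no group terms in the design)
        rng = np.random.default_rng(3)
        rows = []
        for i in range(3):
            ai = rng.normal(0, 1.5)
            for t in range(1, 5):
                rows.append((f"p{i}", t, 2.0 + 0.4 * t + ai + rng.normal(0, 1.0), 0.0))
        df = lmm_frame(rows)
        fit = fit_mixed_model(df, SPEC_NO_COV)
        beta = np.array([fit.params["intercept"], fit.params["day"]])
        oracle = direct_loglik(df, beta, fit.sigma2, fit.mu2, ["day"])
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_local_optimality_probe(self):
        # the MLE beats every perturbed parameter vector on a seeded grid
        rng = np.random.default_rng(4)
        rows = []
        for i in range(4):
            ai = rng.normal(0, 1.0)
            for t in range(1, 6):
                g = float(i >= 2)
                rows.append((f"p{i}", t, 1.0 + 0.3 * t + g + 0.2 * t * g + ai + rng.normal(0, 0.8), g))
        df = lmm_frame(rows)  # 20 observations
        fit = fit_mixed_model(df, SPEC_NO_COV)
        beta_hat = np.array([fit.params[k] for k in ("intercept", "day", "group", "day:group")])
        df2 = df.assign(**{"day:group": df.day * df.group})
        best = direct_loglik(df2, beta_hat, fit.sigma2, fit.mu2, ["day", "group", "day:group"])
        perturb_rng = np.random.default_rng(99)
        for _ in range(40):
            delta = perturb_rng.normal(0, 0.3, size=4)
            s2 = fit.sigma2 * math.exp(perturb_rng.normal(0, 0.2))
            m2 = max(fit.mu2 * math.exp(perturb_rng.normal(0, 0.2)), 1e-8)
            ll = direct_loglik(df2, beta_hat + delta, s2, m2, ["day", "group", "day:group"])
            assert best >= ll - 1e-9

    def test_estimates_within_3se_of_truth(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(60):
            ai = rng.normal(0, 2.0)
            g = float(i >= 30)
            for t in range(1, 9):
                rows.append((f"p{i}", t, 1.0 + 0.5 * t + 2.0 * g + 0.3 * t * g + ai + rng.normal(0, 1.0), g))
        fit = fit_mixed_model(lmm_frame(rows), SPEC_NO_COV)
        for term, truth in (("day", 0.5), ("group", 2.0), ("day:group", 0.3)):
            assert abs(fit.params[term] - truth) < 3 * fit.se(term)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.3)
        assert fit.mu2 == pytest.approx(4.0, rel=0.5)

    def test_requires_two_patients_per_group(self):
        df = lmm_frame([("a", 1, 1.0, 0), ("a", 2, 2.0, 0), ("b", 1, 1.0, 1), ("b", 2, 2.0, 1)])
        with pytest.raises(ValueError, match="2 patients"):
            fit_mixed_model(df, SPEC_NO_COV)

    def test_day_range_filter(self):
        df = exact_linear_frame(days=10)
        spec = ModelSpec(day_range=(1, 5), covariates=())
        fit = fit_mixed_model(df, spec)
        assert fit.n_obs == 6 * 5

    def test_covariates_centered(self):
        rng = np.random.default_rng(5)
        rows = []
        ages = {}
        for i in range(8):
            g = float(i >= 4)
            ages[f"p{i}"] = 50.0 + 2.0 * i
            for t in range(1, 5):
                rows.append((f"p{i}", t, 1.0 + 0.5 * t + g + rng.normal(0, 0.1), g))
        df = lmm_frame(rows)
        df["age"] = df.patient_id.map(ages)
        df["gender"] = ["male" if int(p[1:]) % 2 else "female" for p in df.patient_id]
        fit = fit_mixed_model(df, ModelSpec(day_range=(1, 60)))
        assert "age" in fit.params and "gender" in fit.params
        assert fit.covariate_means["age"] == pytest.approx(df.age.mean())


# --- residual diagnostics --------------------------------------------------


class TestResidualDiagnostics:
    def test_noiseless_zero_residuals(self):
        fit = fit_mixed_model(exact_linear_frame(), SPEC_NO_COV)
        diag = residual_diagnostics(fit)
        assert np.allclose(diag.resid, 0.0, atol=1e-8)

    def test_gaussian_slope_near_zero(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(30):
            g = float(i >= 15)
            for t in range(1, 11):
                rows.append((f"p{i}", t, 1 + 0.5 * t + g + 0.1 * t * g + rng.normal(0, 1.0), g))
        diag = residual_diagnostics(fit_mixed_model(lmm_frame(rows), SPEC_NO_COV))
        assert abs(diag.resid_fitted_slope) < 2 * diag.resid_fitted_slope_se

    def test_heavy_tails_raise_qq_deviation(self):
        rng = np.random.default_rng(22)

        def fit_with(noise):
            rows = []
            for i in range(30):
                g = float(i >= 15)
                for t in range(1, 11):
                    rows.append((f"p{i}", t, 1 + 0.5 * t + g + 0.1 * t * g + noise(), g))
            return fit_mixed_model(lmm_frame(rows), SPEC_NO_COV)

        gauss = residual_diagnostics(fit_with(lambda: rng.normal(0, 1.0)))
        heavy = residual_diagnostics(fit_with(lambda: rng.standard_t(1.5)))
        assert heavy.qq_deviation > gauss.qq_deviation


# --- preop reference -------------------------------------------------------


def test_preop_reference_equal_patient_weighting():
    rows = []
    for pid, vals in (("a", [100, 110]), ("b", [200.0]), ("c", [300, 300, 300])):
        for i, v in enumerate(vals):
            rows.append(dict(patient_id=pid, day_post_op=-(i + 1), steps=v))
    refs = preop_reference(pd.DataFrame(rows), "steps", {"a": "G", "b": "G", "c": "G"})
    # mean of per-patient means, NOT the pooled mean
    assert refs["G"].mean == pytest.approx((105 + 200 + 300) / 3)
    assert refs["G"].n_patients == 3
    assert refs["G"].ci_low < refs["G"].mean < refs["G"].ci_high


def test_preop_reference_requires_preop_days():
    df = pd.DataFrame([dict(patient_id="a", day_post_op=3, steps=100.0)])
    with pytest.raises(ValueError):
        preop_reference(df, "steps", {"a": "G"})


# --- time_to_preop_return --------------------------------------------------


def affine_fit(alpha, slope):
    return make_fit(
        {
            "intercept": (alpha, 1e-12),
            "day": (slope, 1e-12),
            "group": (0.0, 1e-12),
            "day:group": (0.0, 1e-12),
        }
    )


def ref(mean):
    return PreopReference(group="G", mean=mean, ci_low=mean - 1, ci_high=mean + 1, n_patients=10)


class TestTimeToPreopReturn:
    @pytest.mark.parametrize("baseline,slope", [(33.0, 1.0), (10.0, 0.3), (100.0, 7.0)])
    def test_affine_closed_form(self, baseline, slope):
        fit = affine_fit(0.0, slope)
        est = time_to_preop_return(
            fit, "G", 0.0, baseline_offset=0.0, preop=ref(baseline),
            day_range=(1, 200), n_boot=50, rng=np.random.default_rng(0),
        )
        assert est.day == math.ceil(baseline / slope)

    def test_not_reached(self):
        fit = affine_fit(0.0, -1.0)
        est = time_to_preop_return(
            fit, "G", 0.0, 0.0, ref(10.0), (1, 60), n_boot=50, rng=np.random.default_rng(0)
        )
        assert est.day is None and not est.reached

    def test_baseline_offset_shifts_target(self):
        # un-normalized trajectory = pred + offset; crossing when pred >= mean - offset
        fit = affine_fit(0.0, 1.0)
        est = time_to_preop_return(
            fit, "G", 0.0, baseline_offset=20.0, preop=ref(50.0),
            day_range=(1, 100), n_boot=50, rng=np.random.default_rng(0),
        )
        assert est.day == 30

    def test_bootstrap_ci_brackets_day(self):
        fit = make_fit(
            {
                "intercept": (0.0, 4.0),
                "day": (1.0, 0.001),
                "group": (0.0, 1e-12),
                "day:group": (0.0, 1e-12),
            }
        )
        est = time_to_preop_return(
            fit, "G", 0.0, 0.0, ref(30.0), (1, 100), n_boot=2000, rng=np.random.default_rng(1)
        )
        assert est.ci_low <= est.day <= est.ci_high
        assert est.ci_low < est.ci_high  # genuine spread from vcov


# --- group_separation_day --------------------------------------------------


class TestGroupSeparationDay:
    def test_null_case_not_reached(self):
        fit = make_fit(
            {
                "intercept": (0.0, 1.0),
                "day": (1.0, 0.01),
                "group": (0.0, 1.0),
                "day:group": (0.0, 0.01),
            }
        )
        est = group_separation_day(fit, (1, 60), rng=np.random.default_rng(0))
        assert est.day is None

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(77)
        z = float(norm.ppf(0.975))
        for _ in range(25):
            b2 = rng.normal(0, 2)
            b3 = rng.normal(0, 0.3)
            A = rng.normal(0, 1, (2, 2))
            V = A @ A.T + 1e-6 * np.eye(2)
            scale = 10 ** rng.uniform(-4, 0)
            v22, v23, v33 = V[0, 0] * scale, V[0, 1] * scale, V[1, 1] * scale * 1e-3
            got = separation_scan(b2, b3, v22, v23, v33, (1, 90), z)
            expected = closed_form_separation(b2, b3, v22, v23, v33, (1, 90), z)
            assert got == expected

    def test_doubling_interaction_never_later(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            b2, b3 = rng.normal(0, 1), abs(rng.normal(0.1, 0.2))
            v22, v23, v33 = 0.5, 0.01, 0.002
            z = 1.96
            d1 = separation_scan(b2, b3, v22, v23, v33, (1, 90), z)
            d2 = separation_scan(b2, 2 * b3, v22, v23, v33, (1, 90), z)
            if d1 is not None:
                assert d2 is not None and d2 <= d1

    def test_fit_without_group_terms_raises(self):
        fit = make_fit({"intercept": (0.0, 1.0), "day": (1.0, 0.01)})
        with pytest.raises(ValueError, match="group"):
            group_separation_day(fit, (1, 60))


def test_predict_group_trajectory_linear():
    fit = make_fit(
        {
            "intercept": (1.0, 0.0),
            "day": (2.0, 0.0),
            "group": (10.0, 0.0),
            "day:group": (0.5, 0.0),
        }
    )
    days = np.array([1, 2, 3])
    np.testing.assert_allclose(predict_group_trajectory(fit, 0.0, days), 1 + 2 * days)
    np.testing.assert_allclose(predict_group_trajectory(fit, 1.0, days), 11 + 2.5 * days)
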