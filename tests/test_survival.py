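import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from survgwas.survival import (
    ConvergenceError,
    cohort_null_residuals,
    cox_carrier_hr,
    cox_score_test,
    fit_cox,
    kaplan_meier,
    logrank_test,
    martingale_residuals,
)

from conftest import toy_cohort


def brute_force_partial_loglik(beta, times, events, x):
    """Explicit one-covariate Cox partial likelihood (Breslow), written
    directly from the definition as an independent oracle."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestFitCox:
    def test_one_covariate_matches_brute_force(self):
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(times, events, x, ties="breslow")
        res = minimize_scalar(
            lambda b: -brute_force_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta_hat[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_lifelines(self, rng):
        import lifelines

        n = 400
        x = rng.binomial(1, 0.4, n).astype(float)
        z = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x + 0.2 * z))
        d = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox(t, d, np.column_stack([x, z]), ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": d, "x": x, "z": z}), "t", "e")
        np.testing.assert_allclose(fit.beta_hat, cph.params_[["x", "z"]], rtol=1e-5)
        np.testing.assert_allclose(fit.se_beta(), cph.standard_errors_[["x", "z"]], rtol=1e-4)

    def test_null_model_baseline_is_nelson_aalen(self):
        from lifelines import NelsonAalenFitter

        t = np.array([1.0, 2.0, 2.0, 4.0, 6.0, 9.0])
        d = np.array([1, 1, 0, 1, 1, 0])
        fit = fit_cox(t, d, None)
        assert fit.beta_hat.size == 0
        naf = NelsonAalenFitter()
        naf.fit(t, d)
        for time, h in zip(fit.baseline_times, fit.baseline_cumhaz):
            assert h == pytest.approx(
                naf.cumulative_hazard_.loc[time].iloc[0], rel=1e-10
            )

    def test_efron_breslow_agree_without_ties(self, rng):
        n = 150
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.3 * x))
        d = (rng.random(n) < 0.6).astype(int)
        f1 = fit_cox(t, d, x, ties="efron")
        f2 = fit_cox(t, d, x, ties="breslow")
        assert f1.beta_hat[0] == pytest.approx(f2.beta_hat[0], abs=1e-10)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_cox([1.0, 2.0], [0, 0], [0.0, 1.0])

    def test_collinear_covariates_error(self, rng):
        x = rng.standard_normal(20)
        t = rng.exponential(1, 20)
        d = np.ones(20, dtype=int)
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(t, d, np.column_stack([x, 2 * x]))

    def test_separation_raises(self):
        # every carrier censored before the first non-carrier event
        t = np.array([1.0, 2.0, 5.0, 6.0, 7.0, 8.0])
        d = np.array([0, 0, 1, 1, 1, 1])
        x = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError):
            fit_cox(t, d, x)

    def test_loglik_improves_on_null(self, rng):
        n = 200
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(np.exp(-0.8 * x))
        d = np.ones(n, dtype=int)
        fit = fit_cox(t, d, x)
        ll0 = brute_force_partial_loglik(0.0, t, d, x)
        assert fit.loglik >= ll0


class TestMartingaleResiduals:
    def test_hand_example(self):
        fit = fit_cox([1.0, 2.0, 3.0], [1, 1, 0], None, ties="breslow")
        r = martingale_residuals(fit, [1.0, 2.0, 3.0], [1, 1, 0], None)
        np.testing.assert_allclose(r, [2 / 3, 1 / 6, -5 / 6], rtol=1e-12)

    def test_censored_before_first_event_zero(self):
        fit = fit_cox([5.0, 6.0, 7.0], [1, 1, 1], None, ties="breslow")
        r = martingale_residuals(fit, [1.0], [0], None)
        assert r[0] == 0.0

    def test_sum_zero_and_upper_bound(self, rng):
        """Breslow estimating-equation identity on randomly fitted models."""
        for seed in range(5):
            rg = np.random.default_rng(seed)
            n = 120
            Z = rg.standard_normal((n, 2))
            t = rg.exponential(np.exp(-(Z @ [0.4, -0.2])))
            d = (rg.random(n) < 0.7).astype(int)
            if d.sum() == 0:
                continue
            fit = fit_cox(t, d, Z, ties="breslow")
            r = martingale_residuals(fit, t, d, Z)
            assert abs(r.sum()) < 1e-8
            assert r.max() <= 1.0 + 1e-12

    def test_time_beyond_range_uses_last_step(self):
        fit = fit_cox([1.0, 2.0], [1, 1], None)
        r = martingale_residuals(fit, [100.0], [0], None)
        assert r[0] == pytest.approx(-fit.baseline_cumhaz[-1])


class TestKaplanMeierLogrank:
    def test_no_events_flat_curve(self):
        curves = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curves[0].survival == 1.0).all()

    def test_hand_product_limit(self):
        # events at 1 and 2, censored at 1.5 and 3
        curves = kaplan_meier([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        c = curves[0]
        s = dict(zip(c.times, c.survival))
        assert s[1.0] == pytest.approx(3 / 4)
        assert s[2.0] == pytest.approx(3 / 8)  # risk set of 2 at t=2

    def test_all_events_same_time_single_step(self):
        curves = kaplan_meier([2.0, 2.0, 2.0], [1, 1, 1])
        assert curves[0].survival[-1] == pytest.approx(0.0)

    def test_survival_monotone_nonincreasing(self, rng):
        t = rng.exponential(1, 100)
        d = (rng.random(100) < 0.5).astype(int)
        c = kaplan_meier(t, d)[0]
        assert (np.diff(c.survival) <= 1e-12).all()
        assert c.survival[0] <= 1.0

    def test_identical_groups_statistic_zero(self):
        t = np.r_[[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]
        d = np.r_[[1, 0, 1, 1], [1, 0, 1, 1]]
        g = np.r_[np.zeros(4), np.ones(4)]
        chi2, p = logrank_test(t, d, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_score_test_equals_logrank_no_ties(self, rng):
        n = 80
        g = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(np.exp(-0.6 * g))
        d = (rng.random(n) < 0.8).astype(int)
        chi2_score, _ = cox_score_test(t, d, g, ties="breslow")
        chi2_lr, _ = logrank_test(t, d, g)
        assert chi2_score == pytest.approx(chi2_lr, rel=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCarrierHr:
    def test_recovers_generative_hr(self, rng):
        n = 4000
        cohort = toy_cohort(n, seed=9, frac_events=0.0)
        carrier = rng.binomial(1, 0.1, n)
        eta = np.log(2.0) * carrier + 0.2 * cohort["sex"].to_numpy()
        cohort["age"] = rng.exponential(np.exp(-eta)) * 50 + 1
        cohort["event"] = 1
        res = cox_carrier_hr(cohort, carrier)
        assert res["hr"] == pytest.approx(2.0, rel=0.2)
        assert res["ci"][0] < res["hr"] < res["ci"][1]

    def test_no_carriers_errors(self):
        cohort = toy_cohort(50)
        with pytest.raises(ValueError, match="carrier"):
            cox_carrier_hr(cohort, np.zeros(50))


class TestNullResiduals:
    def test_residuals_align_and_sum_zero(self):
        cohort = toy_cohort(300, seed=1)
        fit, resid = cohort_null_residuals(cohort)
        assert resid.size == len(cohort)
        assert abs(resid.sum()) < 1e-8
        assert fit.covariate_names == ["sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
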