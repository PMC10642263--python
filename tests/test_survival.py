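"""Survival curves, censored fitting and model selection.

Closed-form curve values are checked against scipy's distributions in the
matching parameterisation, and maximum-likelihood fits against lifelines'
fitters, so every numeric assertion has an independent oracle.
"""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter
from scipy import integrate, stats

from npc_cea import (CensoredObservation, Family, SurvivalCurveParams,
                     cycle_transition_prob, fit_all_families, fit_censored,
                     log_likelihood, read_ipd, select_family, simulate_ipd,
                     write_ipd)
from npc_cea.survival import FitResult, N_PARAMS

T_GRID = np.array([0.0, 0.1, 0.5, 1.0, 2.5, 6.0, 12.0, 24.0, 60.0])


class TestCurveValuesAgainstScipy:
    def test_weibull_matches_scipy(self):
        lam, gam = 0.005008, 1.297713
        curve = SurvivalCurveParams("weibull", lam, gam)
        # S(t) = exp(-lam t^gam)  <=>  weibull_min with c=gam, scale=lam^(-1/gam)
        expected = stats.weibull_min.sf(T_GRID, c=gam, scale=lam ** (-1.0 / gam))
        np.testing.assert_allclose(curve.survival_at(T_GRID), expected, rtol=1e-12)

    def test_exponential_matches_scipy(self):
        lam = 0.23
        curve = SurvivalCurveParams("exponential", lam)
        np.testing.assert_allclose(curve.survival_at(T_GRID),
                                   stats.expon.sf(T_GRID, scale=1 / lam), rtol=1e-12)

    def test_log_logistic_matches_scipy_fisk(self):
        lam, gam = 0.08, 1.4
        curve = SurvivalCurveParams("log-logistic", lam, gam)
        expected = stats.fisk.sf(T_GRID, c=gam, scale=1 / lam)
        np.testing.assert_allclose(curve.survival_at(T_GRID), expected, rtol=1e-12)

    def test_log_normal_matches_scipy(self):
        mu, sigma = 2.1, 0.8
        curve = SurvivalCurveParams("log-normal", mu, sigma)
        expected = stats.lognorm.sf(T_GRID, s=sigma, scale=math.exp(mu))
        np.testing.assert_allclose(curve.survival_at(T_GRID), expected, rtol=1e-12)

    def test_gompertz_survival_integrates_its_hazard(self):
        # no scipy twin in this parameterisation: check -log S = integral of h
        curve = SurvivalCurveParams("gompertz", 0.02, 0.15)
        for t in (0.5, 3.0, 11.0):
            cum, _ = integrate.quad(curve.hazard_at, 0.0, t)
            assert math.isclose(-math.log(curve.survival_at(t)), cum, rel_tol=1e-8)

    def test_survival_at_zero_is_one(self):
        for fam, scale, shape in [("exponential", 0.2, 1.0), ("weibull", 0.1, 1.5),
                                  ("log-logistic", 0.1, 1.5), ("gompertz", 0.1, 0.2),
                                  ("log-normal", 1.0, 0.5)]:
            assert SurvivalCurveParams(fam, scale, shape).survival_at(0.0) == 1.0


class TestHazardAndQuantile:
    @pytest.mark.parametrize("fam,scale,shape", [
        ("exponential", 0.2, 1.0), ("weibull", 0.03, 1.6),
        ("log-logistic", 0.08, 1.4), ("gompertz", 0.02, 0.15),
        ("log-normal", 2.1, 0.8)])
    def test_hazard_is_negative_log_survival_slope(self, fam, scale, shape):
        curve = SurvivalCurveParams(fam, scale, shape)
        t, h = 5.0, 1e-6
        slope = (math.log(curve.survival_at(t - h)) - math.log(curve.survival_at(t + h))) / (2 * h)
        assert math.isclose(curve.hazard_at(t), slope, rel_tol=1e-5)

    @pytest.mark.parametrize("fam,scale,shape", [
        ("exponential", 0.2, 1.0), ("weibull", 0.03, 1.6),
        ("log-logistic", 0.08, 1.4), ("gompertz", 0.02, 0.15),
        ("log-normal", 2.1, 0.8)])
    def test_quantile_inverts_survival(self, fam, scale, shape):
        curve = SurvivalCurveParams(fam, scale, shape)
        for p in (0.9, 0.5, 0.1, 0.01):
            assert math.isclose(curve.survival_at(curve.quantile(p)), p, rel_tol=1e-10)

    def test_weibull_median_closed_form(self):
        lam, gam = 0.034444, 1.615226
        curve = SurvivalCurveParams("weibull", lam, gam)
        assert math.isclose(curve.median, (math.log(2) / lam) ** (1 / gam), rel_tol=1e-12)

    def test_exponential_constant_hazard(self):
        curve = SurvivalCurveParams("exponential", 0.37)
        np.testing.assert_allclose(curve.hazard_at(np.array([0.1, 2.0, 50.0])), 0.37)


class TestParameterValidation:
    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            SurvivalCurveParams("weibull", -0.1, 1.0)
        with pytest.raises(ValueError):
            SurvivalCurveParams("weibull", 0.0, 1.0)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            SurvivalCurveParams("weibull", 0.1, 0.0)
        with pytest.raises(ValueError):
            SurvivalCurveParams("log-normal", 1.0, -0.5)

    def test_log_normal_location_may_be_negative(self):
        assert SurvivalCurveParams("log-normal", -1.5, 0.5).survival_at(1.0) > 0

    def test_exponential_shape_fixed(self):
        with pytest.raises(ValueError):
            SurvivalCurveParams("exponential", 0.1, 2.0)

    def test_rejects_negative_time(self):
        curve = SurvivalCurveParams("weibull", 0.1, 1.5)
        with pytest.raises(ValueError):
            curve.survival_at(-1.0)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError):
            SurvivalCurveParams("cauchy", 0.1, 1.0)


class TestLogLikelihood:
    def test_matches_manual_weibull_likelihood(self):
        lam, gam = 0.03, 1.6
        curve = SurvivalCurveParams("weibull", lam, gam)
        times = np.array([2.0, 5.0, 9.0, 12.0])
        events = np.array([True, False, True, False])
        c = lam ** (-1.0 / gam)
        manual = (stats.weibull_min.logpdf(times[events], c=gam, scale=c).sum()
                  + stats.weibull_min.logsf(times[~events], c=gam, scale=c).sum())
        assert math.isclose(log_likelihood(curve, times, events), manual, rel_tol=1e-10)

    def test_censoring_only_contributes_survival(self):
        curve = SurvivalCurveParams("exponential", 0.5)
        ll = log_likelihood(curve, [4.0], [False])
        assert math.isclose(ll, math.log(curve.survival_at(4.0)), rel_tol=1e-12)


@pytest.fixture(scope="module")
def weibull_ipd():
    true = SurvivalCurveParams("weibull", 0.001060, 2.027554)
    return simulate_ipd(true, n=800, censor_time=24.0, seed=11)


class TestFitting:
    def test_weibull_fit_matches_lifelines(self, weibull_ipd):
        ours = fit_censored(weibull_ipd, "weibull")
        lf = WeibullFitter().fit(weibull_ipd["time_months"], weibull_ipd["event"])
        # lifelines: S = exp(-(t/lambda_)^rho_)  => our scale = lambda_^-rho_
        np.testing.assert_allclose(ours.params.shape, lf.rho_, rtol=1e-4)
        np.testing.assert_allclose(ours.params.scale, lf.lambda_ ** -lf.rho_, rtol=1e-3)
        assert math.isclose(ours.log_likelihood, lf.log_likelihood_, rel_tol=1e-8)

    def test_log_normal_fit_matches_lifelines(self, weibull_ipd):
        ours = fit_censored(weibull_ipd, "log-normal")
        lf = LogNormalFitter().fit(weibull_ipd["time_months"], weibull_ipd["event"])
        np.testing.assert_allclose(ours.params.scale, lf.mu_, rtol=1e-4)
        np.testing.assert_allclose(ours.params.shape, lf.sigma_, rtol=1e-4)
        assert math.isclose(ours.log_likelihood, lf.log_likelihood_, rel_tol=1e-8)

    def test_log_logistic_fit_matches_lifelines(self, weibull_ipd):
        ours = fit_censored(weibull_ipd, "log-logistic")
        lf = LogLogisticFitter().fit(weibull_ipd["time_months"], weibull_ipd["event"])
        # lifelines: S = 1/(1 + (t/alpha_)^beta_)  => our lam = 1/alpha_
        np.testing.assert_allclose(ours.params.scale, 1.0 / lf.alpha_, rtol=1e-3)
        np.testing.assert_allclose(ours.params.shape, lf.beta_, rtol=1e-3)
        assert math.isclose(ours.log_likelihood, lf.log_likelihood_, rel_tol=1e-8)

    def test_information_criteria_formulas(self, weibull_ipd):
        fit = fit_censored(weibull_ipd, "weibull")
        k, n = N_PARAMS[Family.WEIBULL], len(weibull_ipd)
        assert math.isclose(fit.aic, 2 * k - 2 * fit.log_likelihood, rel_tol=1e-12)
        assert math.isclose(fit.bic, k * math.log(n) - 2 * fit.log_likelihood,
                            rel_tol=1e-12)

    def test_accepts_observation_sequence(self):
        obs = [CensoredObservation(t, e) for t, e in
               zip([1.0, 2.0, 3.0, 4.0, 6.0, 9.0], [1, 1, 0, 1, 1, 0])]
        fit = fit_censored(obs, "exponential")
        # exponential MLE has closed form: events / total time
        assert math.isclose(fit.params.scale, 4 / 25.0, rel_tol=1e-5)

    def test_rejects_all_censored(self):
        obs = [CensoredObservation(1.0, False), CensoredObservation(2.0, False)]
        with pytest.raises(ValueError, match="censored"):
            fit_censored(obs, "weibull")

    def test_rejects_single_observation(self):
        with pytest.raises(ValueError):
            fit_censored([CensoredObservation(1.0, True)], "weibull")

    def test_fit_all_families_returns_all_five(self, weibull_ipd):
        fits = fit_all_families(weibull_ipd)
        assert {f.params.family for f in fits} == set(Family)


class TestSelection:
    def test_selects_minimum_aic(self, weibull_ipd):
        fits = fit_all_families(weibull_ipd)
        best = select_family(fits, "aic")
        assert best.aic == min(f.aic for f in fits)

    def test_bic_criterion(self, weibull_ipd):
        fits = fit_all_families(weibull_ipd)
        best = select_family(fits, "bic")
        assert best.bic == min(f.bic for f in fits)

    def test_exact_tie_broken_by_family_order(self):
        p_exp = SurvivalCurveParams("exponential", 0.1)
        p_wei = SurvivalCurveParams("weibull", 0.1, 1.2)
        a = FitResult(p_wei, -100.0, 42.0, 45.0, 50)
        b = FitResult(p_exp, -100.0, 42.0, 45.0, 50)
        assert select_family([a, b]).params.family is Family.EXPONENTIAL

    def test_rejects_empty_and_unknown_criterion(self, weibull_ipd):
        with pytest.raises(ValueError):
            select_family([])
        with pytest.raises(ValueError):
            select_family(fit_all_families(weibull_ipd), "dic")


class TestCycleTransitionProb:
    def test_exponential_gives_constant_probability(self):
        lam, c = 0.1, 1.38
        curve = SurvivalCurveParams("exponential", lam)
        expected = 1.0 - math.exp(-lam * c)
        for k in (1, 5, 40):
            assert math.isclose(cycle_transition_prob(curve, k, c), expected,
                                rel_tol=1e-12)

    def test_matches_conditional_survival_ratio(self):
        curve = SurvivalCurveParams("weibull", 0.005008, 1.297713)
        k, c = 7, 1.0
        expected = 1.0 - curve.survival_at(k * c) / curve.survival_at((k - 1) * c)
        assert math.isclose(cycle_transition_prob(curve, k, c), expected, rel_tol=1e-12)

    def test_probability_in_unit_interval(self):
        curve = SurvivalCurveParams("gompertz", 0.05, 0.3)
        for k in range(1, 60):
            assert 0.0 <= cycle_transition_prob(curve, k, 1.0) <= 1.0

    def test_absorbed_cohort_returns_one(self):
        curve = SurvivalCurveParams("weibull", 5.0, 3.0)  # survival underflows fast
        assert cycle_transition_prob(curve, 500, 10.0) == 1.0

    def test_rejects_bad_arguments(self):
        curve = SurvivalCurveParams("exponential", 0.1)
        with pytest.raises(ValueError):
            cycle_transition_prob(curve, 0, 1.0)
        with pytest.raises(ValueError):
            cycle_transition_prob(curve, 1, 0.0)


class TestIPDRoundTrip:
    def test_write_then_read_preserves_data(self, tmp_path, weibull_ipd):
        path = tmp_path / "ipd.csv"
        write_ipd(weibull_ipd, path)
        back = read_ipd(path)
        pd.testing.assert_frame_equal(back, weibull_ipd[["time_months", "event"]])

    def test_read_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_months\n1.0\n")
        with pytest.raises(ValueError, match="event"):
            read_ipd(path)
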