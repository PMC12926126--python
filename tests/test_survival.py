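"""Survival model zoo: likelihoods, information criteria, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import (ExponentialFitter, LogLogisticFitter, LogNormalFitter,
                       WeibullFitter)

from survcea.ipd import PseudoIPD
from survcea.survival import (FAMILIES, FitError, FitSettings, fit_all,
                              fit_model, information_table, median_survival,
                              select_best, survival_at)

from conftest import weibull_arm


class TestExponentialOracle:
    def test_closed_form_mle_and_information(self):
        """lambda = d / sum(t); events (1,2,3) give lambda = 0.5."""
        ipd = PseudoIPD(((1.0, 1), (2.0, 1), (3.0, 1)), "a", "OS")
        f = fit_model(ipd, "Exponential")
        lam = math.exp(f.params[0])
        ll = 3 * math.log(0.5) - 0.5 * 6
        assert lam == pytest.approx(0.5, abs=1e-6)
        assert f.loglik == pytest.approx(ll, abs=1e-6)
        assert f.aic == pytest.approx(2 * 1 - 2 * ll, abs=1e-6)
        assert f.bic == pytest.approx(math.log(3) - 2 * ll, abs=1e-6)

    def test_censored_closed_form(self):
        """With censoring, lambda = events / total time at risk."""
        ipd = PseudoIPD(((1.0, 1), (2.0, 0), (4.0, 1), (3.0, 0), (5.0, 1)),
                        "a", "OS")
        f = fit_model(ipd, "Exponential")
        assert math.exp(f.params[0]) == pytest.approx(3 / 15, abs=1e-6)


class TestAgainstLifelines:
    """Independent implementations of the classical families."""

    @pytest.mark.parametrize("family,fitter", [
        ("Exponential", ExponentialFitter),
        ("Weibull", WeibullFitter),
        ("Log-normal", LogNormalFitter),
        ("Log-logistic", LogLogisticFitter),
    ])
    def test_loglik_matches(self, weibull_ipd, family, fitter):
        ours = fit_model(weibull_ipd, family)
        ref = fitter().fit(weibull_ipd.times, weibull_ipd.events)
        assert ours.loglik == pytest.approx(ref.log_likelihood_, abs=1e-3)


class TestNestingIdentities:
    def test_rp_hazard_zero_knots_is_weibull(self, weibull_ipd):
        s0 = FitSettings(n_internal_knots=0)
        a = fit_model(weibull_ipd, "RP-hazard", s0)
        b = fit_model(weibull_ipd, "Weibull")
        assert abs(a.loglik - b.loglik) <= 1e-4

    def test_rp_odds_zero_knots_is_loglogistic(self, weibull_ipd):
        s0 = FitSettings(n_internal_knots=0)
        a = fit_model(weibull_ipd, "RP-odds", s0)
        b = fit_model(weibull_ipd, "Log-logistic")
        assert abs(a.loglik - b.loglik) <= 1e-4

    def test_rp_normal_zero_knots_is_lognormal(self, weibull_ipd):
        s0 = FitSettings(n_internal_knots=0)
        a = fit_model(weibull_ipd, "RP-normal", s0)
        b = fit_model(weibull_ipd, "Log-normal")
        assert abs(a.loglik - b.loglik) <= 1e-4

    def test_gengamma_contains_weibull(self, weibull_ipd):
        a = fit_model(weibull_ipd, "GeneralizedGamma")
        b = fit_model(weibull_ipd, "Weibull")
        assert a.loglik >= b.loglik - 1e-4

    def test_mcm_with_vanishing_cure_fraction_is_weibull(self, weibull_ipd):
        a = fit_model(weibull_ipd, "MCM")
        b = fit_model(weibull_ipd, "Weibull")
        # uncensored-tail data push pi to the boundary
        assert a.loglik >= b.loglik - 1e-4

    def test_fp1_with_zero_slope_is_exponential(self):
        """FP1 log h = b0 + 0 * t^p reduces to a constant hazard."""
        from survcea.survival import _FracPoly
        fam = _FracPoly((1.0,))
        lam = 0.35
        theta = np.array([math.log(lam), 0.0])
        S = fam.survival_fn(theta)(np.array([5.0]))[0]
        assert S == pytest.approx(math.exp(-lam * 5.0), abs=1e-6)


class TestSurvivalEvaluator:
    def test_negative_time_errors(self, weibull_ipd):
        f = fit_model(weibull_ipd, "Weibull")
        with pytest.raises(ValueError):
            survival_at(f, -1.0)

    @pytest.mark.parametrize("family", ["Exponential", "Weibull", "Gamma",
                                        "Log-normal", "Gompertz",
                                        "Log-logistic", "GeneralizedGamma",
                                        "FP1", "GAM", "MCM"])
    def test_monotone_and_bounded_on_horizon(self, weibull_ipd, family):
        f = fit_model(weibull_ipd, family)
        grid = np.linspace(0, 130 * 28 * 12 / 365.25, 131)
        s = survival_at(f, grid)
        assert s[0] == 1.0
        assert np.all(s >= 0) and np.all(s <= 1)
        assert np.all(np.diff(s) <= 1e-10)

    def test_exponential_closed_form_value(self):
        ipd = PseudoIPD(((1.0, 1), (2.0, 1), (3.0, 1)), "a", "OS")
        f = fit_model(ipd, "Exponential")
        assert survival_at(f, 2.0) == pytest.approx(math.exp(-1.0), abs=1e-6)

    def test_fp_quadrature_matches_adaptive(self, weibull_ipd):
        """Fixed-node cumulative hazard agrees with adaptive quadrature."""
        f = fit_model(weibull_ipd, "FP1")
        from survcea.survival import _FracPoly
        fam = _FracPoly(tuple(f.meta["powers"]))
        th = np.asarray(f.params)
        for t in (1.0, 5.0, 20.0):
            H_fast = -math.log(max(float(f.survival(np.array([t]))[0]), 1e-300))
            H_ref = fam.cumhaz_quad(th, t)
            assert H_fast == pytest.approx(H_ref, rel=1e-6, abs=1e-9)


class TestFitGuards:
    def test_all_censored_errors(self):
        ipd = PseudoIPD(((1.0, 0), (2.0, 0), (3.0, 0), (4.0, 0)), "a", "OS")
        with pytest.raises(FitError, match="censored"):
            fit_model(ipd, "Weibull")

    def test_too_few_events_for_flexible_family(self):
        ipd = PseudoIPD(((1.0, 1), (2.0, 1), (3.0, 1), (4.0, 0)), "a", "OS")
        with pytest.raises(FitError, match="events"):
            fit_model(ipd, "MCM")

    def test_unknown_family(self, weibull_ipd):
        with pytest.raises(ValueError, match="unknown family"):
            fit_model(weibull_ipd, "Pareto")


class TestInformationTable:
    def test_formula(self, weibull_ipd):
        fits = [fit_model(weibull_ipd, f) for f in ("Exponential", "Weibull")]
        tab = information_table(fits)
        for _, row in tab.iterrows():
            assert row["aic"] == pytest.approx(2 * row["k"] - 2 * row["loglik"])
            assert row["bic"] == pytest.approx(
                row["k"] * math.log(row["n"]) - 2 * row["loglik"])

    def test_canonical_order_and_cardinality(self, weibull_ipd):
        fits = fit_all(weibull_ipd)
        tab = information_table(fits)
        assert list(tab["family"]) == [f for f in FAMILIES if f in set(tab["family"])]
        assert len(tab) == 15

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            information_table([])


def _table(rows):
    return pd.DataFrame(rows, columns=["family", "aic", "bic"])


class TestSelectBest:
    def test_argmin_aic(self):
        t = _table([("Exponential", 131.58, 134.55), ("FP1", 120.42, 126.36),
                    ("MCM", 245.93, 254.84)])
        assert select_best(t) == "FP1"

    def test_tie_broken_by_bic(self):
        t = _table([("Weibull", 100.0, 95.77), ("Gamma", 100.0, 96.00)])
        assert select_best(t) == "Weibull"

    def test_override(self):
        t = _table([("Weibull", 100.0, 104.0), ("Gamma", 90.0, 94.0)])
        assert select_best(t, override="Weibull") == "Weibull"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best(_table([]))


class TestParameterRecovery:
    def test_weibull_median_recovered(self):
        """n=500 Weibull(shape 1.4, median 8): median within 10%."""
        ipd = weibull_arm(12, n=500, shape=1.4, median=8.0)
        f = fit_model(ipd, "Weibull")
        assert median_survival(f) == pytest.approx(8.0, rel=0.10)

    def test_generating_family_ranks_high(self):
        """The generating Weibull sits in the AIC top 3 in >= 80% of
        20 seeded replicates of the full zoo."""
        hits = 0
        for seed in range(1, 21):
            ipd = weibull_arm(seed, n=500, censor_scale=2.0)
            tab = information_table(fit_all(ipd)).sort_values("aic")
            rank = list(tab["family"]).index("Weibull") + 1
            hits += rank <= 3
        assert hits >= 16
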