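"""Sensitivity analyses: tornado, moment matching, PSA, CEAC, threshold."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from survcea.uncertainty import (ParameterSpec, PSAResult, ceac,
                                 default_parameter_specs, moment_match, owsa,
                                 psa, sample_parameter, threshold_price)

WTP = 40_457.32


class TestMomentMatch:
    def test_gamma_from_published_row(self):
        spec = ParameterSpec("folfox_cost_cycle", 86.40, 64.80, 108.00, "gamma")
        dist, (shape, scale) = moment_match(spec)
        se = (108.00 - 64.80) / 3.92
        assert dist == "gamma"
        assert se == pytest.approx(11.0204, abs=1e-4)
        assert shape == pytest.approx(61.466, abs=1e-3)
        assert scale == pytest.approx(1.4056, abs=1e-4)

    def test_beta_from_published_row(self):
        spec = ParameterSpec("utility_pfs", 0.68, 0.51, 0.85, "beta")
        dist, (a, b) = moment_match(spec)
        assert dist == "beta"
        assert a == pytest.approx(18.99, abs=0.01)
        assert b == pytest.approx(8.94, abs=0.01)

    def test_degenerate_interval_is_fixed(self):
        spec = ParameterSpec("x", 0.5, 0.5, 0.5, "beta")
        assert moment_match(spec) == ("fixed", (0.5,))

    def test_infeasible_beta_errors(self):
        spec = ParameterSpec("x", 0.5, 0.0, 1.0, "beta")
        # widen: SE = 1/3.92 -> var 0.065 < 0.25 feasible; force infeasible
        spec2 = ParameterSpec("y", 0.001, 0.0, 0.999, "beta")
        with pytest.raises(ValueError, match="infeasible"):
            moment_match(spec2)

    @pytest.mark.parametrize("name,mean,lo,hi,dist", [
        ("folfox_cost_cycle", 86.40, 64.80, 108.00, "gamma"),
        ("utility_pfs", 0.68, 0.51, 0.85, "beta"),
    ])
    def test_sampling_round_trip(self, name, mean, lo, hi, dist):
        """Sample mean within 3 SE/sqrt(n) of the published mean."""
        spec = ParameterSpec(name, mean, lo, hi, dist)
        rng = np.random.default_rng(99)
        draws = sample_parameter(spec, rng, size=10_000)
        se = (hi - lo) / 3.92
        assert abs(draws.mean() - mean) <= 3 * se / math.sqrt(10_000)


class TestOwsa:
    def test_zero_width_bounds_reproduce_base_case(self, model):
        base = model.evaluate().icer
        specs = [ParameterSpec(n, v, v, v, "fixed")
                 for n, v in model.econ.values.items()]
        for e in owsa(model, specs):
            assert e.icer_low == pytest.approx(base, abs=1e-9)
            assert e.icer_high == pytest.approx(base, abs=1e-9)

    def test_unknown_parameter_named_in_error(self, model):
        with pytest.raises(KeyError, match="no_such_param"):
            owsa(model, [ParameterSpec("no_such_param", 1.0, 0.5, 1.5, "gamma")])

    def test_sorted_by_width_and_key_drivers_on_top(self, model):
        entries = owsa(model)
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)
        top4 = {e.parameter for e in entries[:4]}
        assert top4 == {"utility_pfs", "utility_pd",
                        "ramucirumab_price_per_100mg", "discount_rate"}

    def test_icer_increasing_in_ramucirumab_price(self, model):
        icers = [model.evaluate_at_price_fraction(f).icer
                 for f in (0.75, 1.0, 1.25)]
        assert icers[0] < icers[1] < icers[2]


class TestPsa:
    def test_same_seed_reproduces_draws(self, model):
        a = psa(model, n_draws=40, seed=7)
        b = psa(model, n_draws=40, seed=7)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)

    def test_all_fixed_specs_reproduce_base(self, model):
        base = model.evaluate()
        specs = [ParameterSpec(n, v, v, v, "fixed")
                 for n, v in model.econ.values.items()]
        r = psa(model, specs, n_draws=2, seed=1)
        assert np.allclose(r.delta_cost, base.delta_cost)
        assert np.allclose(r.delta_effect, base.delta_effect)

    def test_draw_count_and_finiteness(self, model):
        r = psa(model, n_draws=64, seed=3)
        assert r.n_draws == 64
        assert np.all(np.isfinite(r.delta_cost))
        assert np.all(np.isfinite(r.delta_effect))


class TestCeac:
    def _psa(self):
        return PSAResult(delta_cost=np.array([100.0, 200.0, 300.0]),
                         delta_effect=np.array([0.1, 0.2, 0.3]), seed=0)

    def test_zero_wtp_with_positive_costs(self):
        assert ceac(self._psa(), [0.0])[0][1] == 0.0

    def test_large_wtp_with_positive_effects(self):
        assert ceac(self._psa(), [1e12])[0][1] == 1.0

    def test_monotone_when_effects_positive(self, model):
        r = psa(model, n_draws=200, seed=11)
        grid = np.linspace(0, 12 * WTP, 40)
        probs = [p for _, p in ceac(r, grid)]
        if np.all(r.delta_effect > 0):
            assert np.all(np.diff(probs) >= 0)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            ceac(self._psa(), [])


class _ToyModel:
    """ICER(f) = (1000 f + 100) / 0.05, linear in the price fraction."""

    def __init__(self):
        self.econ = SimpleNamespace(values={"ramucirumab_price_per_100mg": 616.05})

    def evaluate_at_price_fraction(self, f):
        return SimpleNamespace(icer=(1000.0 * f + 100.0) / 0.05)


class TestThreshold:
    def test_closed_form_bracket(self):
        res = threshold_price(_ToyModel(), target=10_000.0, tol=0.5)
        assert res.status == "converged"
        assert res.fraction == pytest.approx(0.4, abs=1e-4)
        assert res.price_per_100mg == pytest.approx(0.4 * 616.05, rel=1e-3)

    def test_target_below_free_drug_reports_boundary(self):
        res = threshold_price(_ToyModel(), target=1000.0)
        assert res.status == "below_range"
        assert res.fraction is None

    def test_target_above_current_price_reports_boundary(self):
        res = threshold_price(_ToyModel(), target=1e9)
        assert res.status == "above_range"
        assert res.fraction == 1.0

    def test_self_consistency_on_fixture(self, model):
        res = threshold_price(model, WTP)
        assert res.status == "converged"
        icer = model.evaluate_at_price_fraction(res.fraction).icer
        assert abs(icer - WTP) < 0.5

    def test_pap_needs_smaller_nominal_cut(self, model):
        base = threshold_price(model, WTP)
        pap = threshold_price(model.with_pap(), WTP)
        assert pap.fraction > base.fraction


class TestSpecs:
    def test_default_specs_cover_model_parameters(self, model):
        names = {s.name for s in default_parameter_specs()}
        assert names == set(model.econ.values)

    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError):
            ParameterSpec("x", 1.0, 2.0, 3.0, "gamma")
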