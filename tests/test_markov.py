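"""Markov cohort engine: transitions, traces, accumulation, ICER."""

import math

import numpy as np
import pytest

from survcea.economics import CYCLE_YEARS, EconomicInputs
from survcea.markov import (CEAResult, CohortTrace, ModelSettings,
                            accumulate, discount_factor, icer, run_cohort,
                            transition_probs_at)

SETTINGS = ModelSettings()


def const_fn(v):
    return lambda t: np.full_like(np.atleast_1d(np.asarray(t, float)), v)


def exp_fn(rate_per_cycle):
    cm = SETTINGS.cycle_months
    return lambda t: np.exp(-rate_per_cycle * np.atleast_1d(np.asarray(t, float)) / cm)


class TestDiscounting:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_zero_rate_identity(self):
        assert discount_factor(57, 0.0) == 1.0

    def test_one_year_of_cycles(self):
        # 13 cycles = 364 days
        assert discount_factor(13, 0.05) == pytest.approx(
            1.05 ** (-364 / 365.25), abs=1e-12)
        assert discount_factor(13, 0.05) == pytest.approx(0.9525399896932002)

    def test_negative_cycle_errors(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestTransitions:
    def test_no_event_limit_is_identity(self):
        m = transition_probs_at(0, const_fn(1.0), const_fn(1.0),
                                SETTINGS.cycle_months)
        assert np.allclose(m, np.eye(3))

    def test_exponential_closed_form(self):
        """q_death = 1 - e^-0.1, progression the residual of PFS exit."""
        m = transition_probs_at(0, exp_fn(0.2), exp_fn(0.1), SETTINGS.cycle_months)
        q_death = 1 - math.exp(-0.1)
        q_exit = 1 - math.exp(-0.2)
        assert m[0, 2] == pytest.approx(q_death, abs=1e-12)
        assert m[0, 1] == pytest.approx(q_exit - q_death, abs=1e-12)
        assert m[1, 2] == pytest.approx(q_death, abs=1e-12)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_crossing_curves_clamped(self):
        """PFS decaying slower than OS: progression clamps to zero."""
        m = transition_probs_at(0, exp_fn(0.05), exp_fn(0.2), SETTINGS.cycle_months)
        assert m[0, 1] == 0.0
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_revived_survival_errors(self):
        dead_then_alive = lambda t: np.where(
            np.atleast_1d(np.asarray(t, float)) < 0.5, 0.0, 0.5)
        with pytest.raises(ValueError, match="zero"):
            transition_probs_at(0, const_fn(1.0), dead_then_alive,
                                SETTINGS.cycle_months)


class TestCohortTrace:
    def test_conservation_and_monotone_death(self, model):
        for trace in (model.trace_tx, model.trace_ctrl):
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(np.diff(trace.death) >= -1e-12)

    def test_death_matches_os_exactly_without_clamping(self):
        s_pfs, s_os = exp_fn(0.2), exp_fn(0.1)
        trace = run_cohort(s_pfs, s_os, SETTINGS)
        cycles = np.arange(SETTINGS.n_cycles + 1)
        alive = 1.0 - trace.death
        assert np.allclose(alive, np.exp(-0.1 * cycles), atol=1e-9)

    def test_no_progression_degenerate(self):
        s = exp_fn(0.1)
        trace = run_cohort(s, s, SETTINGS)
        assert np.all(trace.pd == 0.0)

    def test_matrix_power_oracle(self):
        """Constant q_death=0.1, q_exit=0.3: trace equals M^t @ (1,0,0)."""
        cm = SETTINGS.cycle_months
        s_pfs = lambda t: 0.7 ** (np.atleast_1d(np.asarray(t, float)) / cm)
        s_os = lambda t: 0.9 ** (np.atleast_1d(np.asarray(t, float)) / cm)
        trace = run_cohort(s_pfs, s_os, SETTINGS)
        M = np.array([[0.7, 0.2, 0.1], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]])
        v = np.array([1.0, 0.0, 0.0])
        for c in range(SETTINGS.n_cycles + 1):
            expected = v @ np.linalg.matrix_power(M, c)
            assert np.allclose(trace.occupancy[c], expected, atol=1e-12)
        # two-cycle hand value
        assert trace.occupancy[2] == pytest.approx([0.49, 0.32, 0.19], abs=1e-12)

    def test_invalid_occupancy_rejected(self):
        occ = np.array([[1.0, 0.0, 0.0], [0.6, 0.3, 0.2]])
        with pytest.raises(ValueError, match="sum"):
            CohortTrace(occ, np.array([0.2]), np.array([0.3]))


def _flat_trace(n, state=(1.0, 0.0, 0.0)):
    occ = np.tile(np.asarray(state, float), (n + 1, 1))
    return CohortTrace(occ, np.zeros(n), np.zeros(n))


class TestAccumulate:
    def test_single_cycle_qaly_closed_form(self):
        """One undiscounted PFS cycle: 0.68 * 28/365.25 QALYs."""
        trace = _flat_trace(1)
        econ = EconomicInputs().with_values(discount_rate=0.0)
        econ = econ.with_values(**{f"risk_{e}_tx": 0.0 for e in
                                   ("neutropenia", "anemia", "neuropathy", "vte")})
        _, q = accumulate(trace, econ, SETTINGS, "treatment")
        assert q == pytest.approx(0.68 * 28 / 365.25, abs=1e-12)

    def test_everyone_dead_costs_end_of_life_only(self):
        occ = np.array([[1.0, 0.0, 0.0]] + [[0.0, 0.0, 1.0]] * 3)
        trace = CohortTrace(occ, np.array([1.0, 0.0, 0.0]), np.zeros(3))
        econ = EconomicInputs().with_values(
            discount_rate=0.0, **{f"risk_{e}_ctrl": 0.0 for e in
                                  ("neutropenia", "anemia", "neuropathy", "vte")})
        c, q = accumulate(trace, econ, SETTINGS, "control")
        # one cycle of PFS drug + monitoring, then end-of-life only
        expected = (econ.values["folfox_cost_cycle"]
                    + econ.monitoring_cost_cycle + econ.eol_cost)
        assert c == pytest.approx(expected, abs=1e-9)
        assert q == pytest.approx(0.68 * 28 / 365.25, abs=1e-12)

    def test_no_discount_flat_occupancy_linear(self):
        n = 10
        trace = _flat_trace(n)
        econ = EconomicInputs().with_values(discount_rate=0.0)
        c1, q1 = accumulate(_flat_trace(1), econ, SETTINGS, "treatment")
        cn, qn = accumulate(trace, econ, SETTINGS, "treatment")
        ae_cost, ae_q = econ.ae_burden("tx")
        assert cn - ae_cost == pytest.approx(n * (c1 - ae_cost), rel=1e-12)
        assert qn + ae_q == pytest.approx(n * (q1 + ae_q), rel=1e-12)

    def test_costs_and_qalys_decrease_with_discount_rate(self, model):
        prev_c, prev_q = math.inf, math.inf
        for r in (0.0, 0.03, 0.05, 0.08):
            res = model.evaluate(model.econ.with_values(discount_rate=r))
            assert res.cost_treatment < prev_c
            assert res.qalys_treatment < prev_q
            prev_c, prev_q = res.cost_treatment, res.qalys_treatment

    def test_control_phase_schedule(self):
        """Doublet for three cycles, fluoropyrimidine afterwards."""
        trace = _flat_trace(5)
        econ = EconomicInputs().with_values(
            discount_rate=0.0, lab_cost=0.0, imaging_cost=0.0,
            **{f"risk_{e}_ctrl": 0.0 for e in
               ("neutropenia", "anemia", "neuropathy", "vte")})
        c, _ = accumulate(trace, econ, SETTINGS, "control")
        assert c == pytest.approx(3 * 86.40 + 2 * 8.80, abs=1e-9)


class TestIcer:
    def test_printed_arm_totals(self):
        res = icer((58186.72, 1.14), (4844.27, 0.75))
        assert res.delta_cost == pytest.approx(53342.45, abs=1e-9)
        assert res.delta_effect == pytest.approx(0.39, abs=1e-9)

    def test_simple_ratio(self):
        assert icer((10, 1.0), (5, 0.5)).icer == pytest.approx(10.0)

    def test_dominant_quadrant(self):
        assert icer((5, 1.0), (10, 0.5)).dominance == "dominant"

    def test_dominated_quadrant(self):
        assert icer((10, 0.5), (5, 1.0)).dominance == "dominated"

    def test_zero_effect_has_no_ratio(self):
        res = icer((10, 0.5), (5, 0.5))
        assert math.isnan(res.icer)
        assert res.dominance == "dominated"

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            icer((math.nan, 1.0), (0.0, 0.5))


class TestSettings:
    def test_cycle_count_for_ten_year_horizon(self):
        assert ModelSettings().n_cycles == 130

    def test_invalid_wtp(self):
        with pytest.raises(ValueError):
            ModelSettings(wtp=0.0)
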