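"""Three-state Markov cohort model: progression-free, progressed, dead.

The cohort enters progression-free and moves between states in 28-day
cycles over a 10-year horizon (130 cycles).  Per-cycle transition
probabilities are read off the selected survival functions: the death
probability comes from the OS curve and applies to both alive states,
and the progression probability is the residual of the PFS exit
probability.  Costs and QALYs are accumulated with annual discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .economics import CYCLE_YEARS, DAYS_PER_YEAR, EconomicInputs

WTP_DEFAULT = 40_457.32  # three times 2024 per-capita GDP, USD/QALY

SurvFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ModelSettings:
    """Cycle structure, horizon and decision threshold."""

    cycle_days: float = 28.0
    horizon_years: float = 10.0
    wtp: float = WTP_DEFAULT
    half_cycle_correction: bool = False
    monitoring_every_n_cycles: int = 1
    pd_treatment_max_cycles: int | None = None
    doublet_cycles: int = 3  # oxaliplatin doublet capped at 12 weeks

    def __post_init__(self) -> None:
        if self.wtp <= 0:
            raise ValueError("WTP threshold must be positive")
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")

    @property
    def n_cycles(self) -> int:
        return int(self.horizon_years * DAYS_PER_YEAR // self.cycle_days)

    @property
    def cycle_months(self) -> float:
        return self.cycle_days * 12.0 / DAYS_PER_YEAR

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR


def discount_factor(cycle: int | np.ndarray, annual_rate: float,
                    cycle_days: float = 28.0) -> float | np.ndarray:
    """(1 + r)^(-cycle * cycle_days / 365.25); 1 at cycle 0 or r = 0."""
    c = np.asarray(cycle, dtype=float)
    if np.any(c < 0):
        raise ValueError("cycle index must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    out = np.power(1.0 + annual_rate, -c * cycle_days / DAYS_PER_YEAR)
    return float(out) if np.isscalar(cycle) else out


def transition_probs_at(cycle: int, s_pfs: SurvFn, s_os: SurvFn,
                        cycle_months: float) -> np.ndarray:
    """3x3 one-cycle transition matrix (rows: PFS, PD, Death).

    q_death = 1 - S_os(t+1)/S_os(t) applies from both alive states;
    progression is the residual of the PFS exit probability and is
    clamped at zero if the curves cross.
    """
    t0, t1 = cycle * cycle_months, (cycle + 1) * cycle_months
    sp0, sp1 = float(s_pfs(np.array([t0]))[0]), float(s_pfs(np.array([t1]))[0])
    so0, so1 = float(s_os(np.array([t0]))[0]), float(s_os(np.array([t1]))[0])
    for a, b, name in ((sp0, sp1, "PFS"), (so0, so1, "OS")):
        if a <= 0 and b > 0:
            raise ValueError(f"{name} survival is zero at cycle {cycle} but "
                             "positive one cycle later")
    q_death = 1.0 - (so1 / so0 if so0 > 0 else 0.0)
    q_exit = 1.0 - (sp1 / sp0 if sp0 > 0 else 0.0)
    q_death = min(max(q_death, 0.0), 1.0)
    q_exit = min(max(q_exit, 0.0), 1.0)
    p_prog = max(0.0, q_exit - q_death)
    p_stay = 1.0 - max(q_exit, q_death)
    m = np.array([
        [p_stay, p_prog, q_death],
        [0.0, 1.0 - q_death, q_death],
        [0.0, 0.0, 1.0],
    ])
    m[0] /= m[0].sum()
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus incident flows."""

    occupancy: np.ndarray          # (n_cycles + 1, 3)
    incident_deaths: np.ndarray    # (n_cycles,)
    incident_progressions: np.ndarray

    def __post_init__(self) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("occupancy rows must sum to 1")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancy outside [0, 1]")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def pfs(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def pd(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def death(self) -> np.ndarray:
        return self.occupancy[:, 2]


def run_cohort(s_pfs: SurvFn, s_os: SurvFn, settings: ModelSettings) -> CohortTrace:
    """Propagate the cohort from (1, 0, 0) over the model horizon."""
    n = settings.n_cycles
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    deaths = np.zeros(n)
    progs = np.zeros(n)
    for c in range(n):
        m = transition_probs_at(c, s_pfs, s_os, settings.cycle_months)
        if np.any(~np.isfinite(m)):
            raise ValueError(f"non-finite transition probabilities at cycle {c}")
        occ[c + 1] = occ[c] @ m
        deaths[c] = occ[c + 1, 2] - occ[c, 2]
        progs[c] = occ[c, 0] * m[0, 1]
    return CohortTrace(occupancy=occ, incident_deaths=deaths,
                       incident_progressions=progs)


def accumulate(trace: CohortTrace, econ: EconomicInputs, settings: ModelSettings,
               arm: str) -> tuple[float, float]:
    """Discounted total cost (USD) and QALYs for one arm.

    Intervention patients receive the maintenance combination while
    progression-free; control patients receive the doublet for the first
    three cycles and fluoropyrimidine maintenance afterwards.  Both arms
    accrue monitoring while alive, the post-progression regimen mix per
    progressed cycle, end-of-life cost at death, and a one-off
    adverse-event cost and QALY decrement at model entry.
    """
    n = len(trace.incident_deaths)
    cycles = np.arange(n)
    df = discount_factor(cycles, econ.discount_rate, settings.cycle_days)
    occ = trace.occupancy
    if settings.half_cycle_correction:
        pfs = 0.5 * (occ[:-1, 0] + occ[1:, 0])
        pd_ = 0.5 * (occ[:-1, 1] + occ[1:, 1])
    else:
        pfs, pd_ = occ[:-1, 0], occ[:-1, 1]

    is_tx = arm in ("tx", "treatment")
    if is_tx:
        drug = np.full(n, econ.pr_cycle_cost(on_treatment=True))
    else:
        drug = np.where(cycles < settings.doublet_cycles,
                        econ.values["folfox_cost_cycle"],
                        econ.values["fu5_cost_cycle"])
    monitor = np.where(cycles % settings.monitoring_every_n_cycles == 0,
                       econ.monitoring_cost_cycle, 0.0)
    pd_costed = pd_.copy()
    cap = settings.pd_treatment_max_cycles
    if cap is not None:
        # approximate cap on post-progression treatment duration: only the
        # occupancy attributable to progressions in the last `cap` cycles
        recent = np.convolve(trace.incident_progressions,
                             np.ones(cap))[:n]
        pd_costed = np.minimum(pd_, recent)
    pd_cost = econ.pd_mix_cost_for_arm("tx" if is_tx else "ctrl")

    cost_c = (pfs * drug + pd_costed * pd_cost + (pfs + pd_) * monitor
              + trace.incident_deaths * econ.eol_cost)
    if np.any(cost_c < -1e-12):
        raise ValueError("negative per-cycle cost component")
    ae_cost, ae_qloss = econ.ae_burden("tx" if is_tx else "ctrl")
    cost = float(np.sum(df * cost_c)) + ae_cost
    u_p, u_d = econ.utility_pfs, econ.utility_pd
    qalys = float(np.sum(df * (pfs * u_p + pd_ * u_d)) * settings.cycle_years) - ae_qloss
    return cost, qalys


@dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted totals and the incremental comparison."""

    cost_treatment: float
    qalys_treatment: float
    cost_control: float
    qalys_control: float

    @property
    def delta_cost(self) -> float:
        return self.cost_treatment - self.cost_control

    @property
    def delta_effect(self) -> float:
        return self.qalys_treatment - self.qalys_control

    @property
    def icer(self) -> float:
        if self.delta_effect == 0:
            return math.nan
        return self.delta_cost / self.delta_effect

    @property
    def dominance(self) -> str:
        dc, de = self.delta_cost, self.delta_effect
        if dc <= 0 and de > 0 or (dc < 0 and de >= 0):
            return "dominant"
        if dc >= 0 and de < 0 or (dc > 0 and de <= 0):
            return "dominated"
        return "tradeoff"

    def verdict(self, wtp: float) -> str:
        if self.dominance == "dominant":
            return "cost-effective (dominant)"
        if self.dominance == "dominated":
            return "not cost-effective (dominated)"
        return ("cost-effective" if self.icer <= wtp else "not cost-effective")


def icer(treated: tuple[float, float], control: tuple[float, float]) -> CEAResult:
    """Incremental comparison of (cost, QALYs) pairs."""
    for v in (*treated, *control):
        if not math.isfinite(v):
            raise ValueError("costs and effects must be finite")
    return CEAResult(cost_treatment=treated[0], qalys_treatment=treated[1],
                     cost_control=control[0], qalys_control=control[1])
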