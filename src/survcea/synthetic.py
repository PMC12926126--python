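"""Synthetic two-arm trial data with the structure the pipeline assumes.

Emulates a maintenance-therapy phase-III trial: two arms, PFS and OS
endpoints, uniform recruitment with administrative censoring, a
digitized Kaplan-Meier curve with at-risk table per arm/endpoint.
Within each arm PFS and OS are coupled comonotonically (one shared
uniform per subject) so no subject progresses after dying; where the
marginal quantile curves cross, PFS is redrawn as a Beta-distributed
fraction of OS.

The default effect sizes put the intervention in the paper's
qualitative regime: a QALY gain bought at a per-QALY cost far above the
willingness-to-pay threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .economics import EconomicInputs
from .ipd import DigitizedCurve, PseudoIPD, km_survival_at
from .markov import ModelSettings


@dataclass(frozen=True)
class Distribution:
    """Generating family with closed-form quantile function."""

    family: str   # weibull | loglogistic | lognormal | exponential
    median: float
    shape: float = 1.0

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Time at which S(t) = 1 - u (u is the failure probability)."""
        u = np.clip(u, 1e-12, 1 - 1e-12)
        m, s = self.median, self.shape
        if self.family == "weibull":
            scale = m / np.log(2.0) ** (1.0 / s)
            return scale * (-np.log1p(-u)) ** (1.0 / s)
        if self.family == "loglogistic":
            return m * (u / (1.0 - u)) ** (1.0 / s)
        if self.family == "lognormal":
            from scipy.stats import norm
            return m * np.exp(s * norm.ppf(u))
        if self.family == "exponential":
            lam = np.log(2.0) / m
            return -np.log1p(-u) / lam
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth for the synthetic trial.

    Medians in months; per-arm sample sizes mirror a 1:1 maintenance
    trial.  Dropout is exponential at 0.01/month on top of
    administrative censoring at 36 months with uniform 18-month
    recruitment.
    """

    pfs_control: Distribution = Distribution("weibull", 6.0, 1.3)
    pfs_treatment: Distribution = Distribution("loglogistic", 9.0, 1.6)
    os_control: Distribution = Distribution("weibull", 12.0, 1.3)
    os_treatment: Distribution = Distribution("lognormal", 16.0, 0.8)
    n_treatment: int = 140
    n_control: int = 136
    admin_censor_months: float = 36.0
    recruitment_months: float = 18.0
    dropout_rate: float = 0.01
    pfs_fraction_beta: tuple[float, float] = (4.0, 1.0)

    def dist(self, arm: str, endpoint: str) -> Distribution:
        key = f"{endpoint.lower()}_{'treatment' if arm in ('tx', 'treatment') else 'control'}"
        return getattr(self, key)

    def n_arm(self, arm: str) -> int:
        return self.n_treatment if arm in ("tx", "treatment") else self.n_control


def _simulate_joint(spec: TruthSpec, arm: str, seed: int):
    """Coupled (pfs, os, censor) latent times for one arm."""
    rng = np.random.default_rng(seed)
    n = spec.n_arm(arm)
    if n <= 0:
        raise ValueError("arm sample size must be positive")
    u = rng.uniform(size=n)
    t_os = spec.dist(arm, "os").quantile(u)
    t_pfs = spec.dist(arm, "pfs").quantile(u)
    bad = t_pfs > t_os
    if bad.any():
        frac = rng.beta(*spec.pfs_fraction_beta, size=int(bad.sum()))
        t_pfs[bad] = t_os[bad] * frac
    entry = rng.uniform(0.0, spec.recruitment_months, size=n)
    admin = spec.admin_censor_months - entry
    dropout = (rng.exponential(1.0 / spec.dropout_rate, size=n)
               if spec.dropout_rate > 0 else np.full(n, np.inf))
    censor = np.minimum(admin, dropout)
    return t_pfs, t_os, censor


def simulate_arm(spec: TruthSpec, arm: str, endpoint: str, seed: int) -> PseudoIPD:
    """Observed (time, event) records for one arm and endpoint."""
    t_pfs, t_os, censor = _simulate_joint(spec, arm, seed)
    t = t_pfs if endpoint.upper() == "PFS" else t_os
    obs = np.minimum(t, censor)
    event = (t <= censor).astype(int)
    obs = np.maximum(obs, 1e-6)
    return PseudoIPD(records=tuple(zip(obs, event)), arm=arm,
                     endpoint=endpoint.upper())


def digitize(ipd: PseudoIPD, grid, risk_times, jitter: float = 0.0,
             seed: int = 0) -> DigitizedCurve:
    """Emulate figure digitization: KM clicks on a grid plus an exact
    at-risk table; optional uniform jitter models extraction error."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty click grid")
    s = km_survival_at(ipd, grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        s = np.clip(s + rng.uniform(-jitter, jitter, size=len(s)), 0.0, 1.0)
    # digitization cannot produce an increasing survival curve
    s = np.minimum.accumulate(s)
    pts = [(0.0, 1.0)] + [(float(t), float(v)) for t, v in zip(grid, s) if t > 0]
    times = ipd.times
    risk = [(float(rt), int(np.sum(times >= rt))) for rt in risk_times]
    risk = [(t, n) for t, n in risk if n > 0]
    return DigitizedCurve(endpoint=ipd.endpoint, arm=ipd.arm,
                          points=tuple(pts), risk_table=tuple(risk))


@dataclass(frozen=True)
class FixtureBundle:
    curves: dict
    truth_ipd: dict
    econ: EconomicInputs
    settings: ModelSettings
    truth: TruthSpec
    seed: int


def make_fixture_study(seed: int = 20240601, jitter: float = 0.002,
                       min_at_risk: int = 10,
                       outdir: str | Path | None = None) -> FixtureBundle:
    """Deterministic end-to-end fixture: four digitized curves, their
    generating truth, default economics and model settings."""
    spec = TruthSpec()
    curves = {}
    truth_ipd = {}
    for i, arm in enumerate(("treatment", "control")):
        arm_seed = (seed + 7919 * i) % 2**31
        for j, endpoint in enumerate(("PFS", "OS")):
            ipd = simulate_arm(spec, arm, endpoint, arm_seed)
            horizon = spec.admin_censor_months
            risk_times = np.arange(0.0, horizon + 1e-9, 3.0)
            # published curves are conventionally truncated once few
            # patients remain at risk
            counts = np.array([np.sum(ipd.times >= rt) for rt in risk_times])
            informative = risk_times[counts >= min_at_risk]
            t_max = float(min(informative[-1] if informative.size else horizon,
                              ipd.times.max()))
            grid = np.linspace(0.5, t_max, 60)
            curves[(arm, endpoint)] = digitize(
                ipd, grid, risk_times, jitter=jitter,
                seed=(arm_seed + j) % 2**31,
            )
            truth_ipd[(arm, endpoint)] = ipd
    bundle = FixtureBundle(curves=curves, truth_ipd=truth_ipd,
                           econ=EconomicInputs(), settings=ModelSettings(),
                           truth=spec, seed=seed)
    if outdir is not None:
        write_fixture(bundle, outdir)
    return bundle


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (arm, endpoint), curve in bundle.curves.items():
        stem = f"{arm}_{endpoint.lower()}"
        with open(out / f"{stem}_curve.csv", "w") as fh:
            fh.write("time_months,survival\n")
            for t, s in curve.points:
                fh.write(f"{t:.6f},{s:.6f}\n")
        with open(out / f"{stem}_risk.csv", "w") as fh:
            fh.write("time_months,n_risk\n")
            for t, n in curve.risk_table:
                fh.write(f"{t:.6f},{n}\n")
    econ = {
        "parameters": {k: float(v) for k, v in bundle.econ.values.items()},
        "profile": {
            "reference_weight_kg": bundle.econ.profile.reference_weight_kg,
            "height_cm": bundle.econ.profile.height_cm,
            "weight_loss": bundle.econ.profile.weight_loss,
        },
        "scenario": {"pap": bundle.econ.pap,
                     "ram_price_fraction": bundle.econ.ram_price_fraction},
    }
    with open(out / "econ.yaml", "w") as fh:
        yaml.safe_dump(econ, fh, sort_keys=True)
    truth = {k: v for k, v in asdict(bundle.truth).items()}
    truth["seed"] = bundle.seed
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
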