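"""Deterministic, probabilistic and threshold sensitivity analyses.

One-way analysis sweeps each parameter to its published bounds (costs
default to +/-25% when no bounds are given) and ranks ICER ranges for a
tornado diagram.  Probabilistic analysis moment-matches Gamma (costs)
and Beta (probabilities/utilities/proportions) distributions to the
published mean and 95% bounds, draws 1,000 parameter vectors, and
summarizes them as a cost-effectiveness acceptability curve.  The
threshold search bisects on the ramucirumab price fraction until the
ICER meets the willingness-to-pay target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEAModel
from .economics import PARAMETER_TABLE

#: bounds are read as a 95% interval: SE = (upper - lower) / 3.92
_Z95_WIDTH = 3.92


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    base: float
    lower: float
    upper: float
    distribution: str  # "gamma" | "beta" | "fixed"
    role: str = "cost"

    def __post_init__(self) -> None:
        if not (self.lower <= self.base <= self.upper):
            raise ValueError(f"{self.name}: bounds must bracket the base value")
        if self.distribution == "beta" and not (0 <= self.lower and self.upper <= 1):
            raise ValueError(f"{self.name}: beta-distributed values must lie in [0, 1]")
        if self.distribution == "gamma" and self.lower < 0:
            raise ValueError(f"{self.name}: gamma-distributed values must be >= 0")


def default_parameter_specs(include_discount: bool = True) -> list[ParameterSpec]:
    """Specs for every published economic parameter."""
    specs = []
    for name, (mean, lo, hi, dist, role) in PARAMETER_TABLE.items():
        if name == "discount_rate" and not include_discount:
            continue
        specs.append(ParameterSpec(name, mean, lo, hi, dist, role))
    return specs


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def owsa(model: CEAModel, specs: list[ParameterSpec] | None = None) -> list[TornadoEntry]:
    """One-way sweep of each parameter to its bounds, all else at base."""
    specs = specs if specs is not None else default_parameter_specs()
    known = set(model.econ.values)
    entries = []
    for spec in specs:
        if spec.name not in known:
            raise KeyError(f"parameter {spec.name!r} unknown to the model")
        lo, hi = spec.lower, spec.upper
        if spec.role == "utility":
            hi = min(hi, 1.0)
        icer_lo = model.evaluate_with(**{spec.name: lo}).icer
        icer_hi = model.evaluate_with(**{spec.name: hi}).icer
        entries.append(TornadoEntry(spec.name, icer_lo, icer_hi))
    entries.sort(key=lambda e: -e.width)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parameter, e.icer_low, e.icer_high, e.width) for e in entries],
        columns=["parameter", "icer_low", "icer_high", "width"],
    )


def moment_match(spec: ParameterSpec) -> tuple[str, tuple[float, ...]]:
    """Distribution parameters matching the published mean and bounds.

    Gamma: shape = mean^2/SE^2, scale = SE^2/mean.  Beta: standard
    method-of-moments.  A zero-width interval collapses to "fixed".
    """
    se = (spec.upper - spec.lower) / _Z95_WIDTH
    if se == 0 or spec.distribution == "fixed":
        return ("fixed", (spec.base,))
    if spec.distribution == "gamma":
        if spec.base <= 0:
            return ("fixed", (spec.base,))
        return ("gamma", (spec.base**2 / se**2, se**2 / spec.base))
    if spec.distribution == "beta":
        m = spec.base
        if not (0 < m < 1):
            return ("fixed", (m,))
        var = se**2
        if var >= m * (1 - m):
            raise ValueError(
                f"{spec.name}: beta moment matching infeasible (SE^2 >= mean(1-mean))"
            )
        nu = m * (1 - m) / var - 1.0
        return ("beta", (m * nu, (1 - m) * nu))
    raise ValueError(f"unknown distribution {spec.distribution!r}")


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator, size=None):
    dist, pars = moment_match(spec)
    if dist == "fixed":
        return np.full(size, pars[0]) if size else pars[0]
    if dist == "gamma":
        return rng.gamma(pars[0], pars[1], size=size)
    return rng.beta(pars[0], pars[1], size=size)


@dataclass(frozen=True)
class PSAResult:
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)


def psa(model: CEAModel, specs: list[ParameterSpec] | None = None,
        n_draws: int = 1000, seed: int = 0,
        include_discount: bool = False) -> PSAResult:
    """Monte-Carlo parameter uncertainty: n_draws model evaluations.

    The discount rate is held at base by default (reference-case
    convention); non-finite draws are rejected and resampled.
    """
    if specs is None:
        specs = default_parameter_specs(include_discount=include_discount)
    rng = np.random.default_rng(seed)
    dcost = np.empty(n_draws)
    deff = np.empty(n_draws)
    i = 0
    attempts = 0
    while i < n_draws:
        attempts += 1
        if attempts > 20 * n_draws:
            raise RuntimeError("too many rejected PSA draws")
        draw = {s.name: float(sample_parameter(s, rng)) for s in specs}
        res = model.evaluate_with(**draw)
        if not (math.isfinite(res.delta_cost) and math.isfinite(res.delta_effect)):
            continue
        dcost[i], deff[i] = res.delta_cost, res.delta_effect
        i += 1
    return PSAResult(delta_cost=dcost, delta_effect=deff, seed=seed)


def ceac(result: PSAResult, wtp_grid) -> list[tuple[float, float]]:
    """P(net monetary benefit > 0) at each willingness-to-pay value."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    out = []
    for lam in grid:
        nmb = lam * result.delta_effect - result.delta_cost
        out.append((float(lam), float(np.mean(nmb > 0))))
    return out


@dataclass(frozen=True)
class ThresholdResult:
    fraction: float | None
    price_per_100mg: float | None
    iterations: int
    status: str  # "converged" | "below_range" | "above_range"


def threshold_price(model: CEAModel, target: float,
                    tol: float = 0.5, max_iter: int = 200) -> ThresholdResult:
    """Price fraction at which the ICER equals the WTP target.

    Bisects on the ramucirumab price fraction in [0, 1]; the ICER is
    monotone non-decreasing in price, so the bracket check at the
    endpoints settles solvability.
    """
    nominal = model.econ.values["ramucirumab_price_per_100mg"]
    icer0 = model.evaluate_at_price_fraction(0.0).icer
    icer1 = model.evaluate_at_price_fraction(1.0).icer
    if icer1 <= target:
        return ThresholdResult(1.0, nominal, 0, "above_range")
    if icer0 >= target:
        return ThresholdResult(None, None, 0, "below_range")
    lo, hi = 0.0, 1.0
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        val = model.evaluate_at_price_fraction(mid).icer
        if abs(val - target) < tol:
            return ThresholdResult(mid, mid * nominal, it, "converged")
        if val > target:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(0.5 * (lo + hi), 0.5 * (lo + hi) * nominal,
                           max_iter, "converged")
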