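"""Dosing, per-cycle regimen costs, adverse-event burdens and utilities.

Costs are direct medical costs in USD from the perspective of a national
healthcare payer.  The maintenance combination (paclitaxel 80 mg/m2 on
days 1, 8, 15 plus ramucirumab 8 mg/kg on days 1 and 15 of each 28-day
cycle) is costed from body-surface-area/weight-based dosing with linear
per-mg pricing; all other regimens carry flat per-cycle costs.

The reference patient weighs 66.9 kg at 163.5 cm; the base case assumes
10% cachexia-related weight loss.  Ramucirumab lists at 616.05 USD per
100 mg; the patient assistance program ("buy two, get one free") makes
the effective maintenance price 2/3 of nominal.  Paclitaxel's per-mg
price is calibrated once so the combination per-cycle cost reproduces
the published 6,011.10 USD at the base-case profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

DAYS_PER_YEAR = 365.25
CYCLE_DAYS = 28.0
CYCLE_YEARS = CYCLE_DAYS / DAYS_PER_YEAR

REFERENCE_WEIGHT_KG = 66.9
REFERENCE_HEIGHT_CM = 163.5
BASE_WEIGHT_LOSS = 0.10

RAMUCIRUMAB_PRICE_PER_100MG = 616.05
PR_CYCLE_COST_BASE = 6011.10  # published combination cost per 28-day cycle
PAP_FACTOR = 2.0 / 3.0


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m2) by the Mosteller formula.

    sqrt(height_cm * weight_kg / 3600); full precision, round only for
    display.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


@dataclass(frozen=True)
class PatientProfile:
    """Anthropometrics driving dose calculations."""

    reference_weight_kg: float = REFERENCE_WEIGHT_KG
    height_cm: float = REFERENCE_HEIGHT_CM
    weight_loss: float = BASE_WEIGHT_LOSS

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight_loss < 1.0):
            raise ValueError("weight_loss must lie in [0, 1)")

    @property
    def weight_kg(self) -> float:
        return self.reference_weight_kg * (1.0 - self.weight_loss)

    @property
    def bsa(self) -> float:
        return bsa_mosteller(self.height_cm, self.weight_kg)


# paclitaxel per-mg price calibrated so the combination per-cycle cost at
# the base-case profile equals the published 6,011.10 USD
_BASE_PROFILE = PatientProfile()
_RAM_MG_BASE = 8.0 * _BASE_PROFILE.weight_kg * 2
_PAC_MG_BASE = 80.0 * _BASE_PROFILE.bsa * 3
PACLITAXEL_PRICE_PER_MG = (
    PR_CYCLE_COST_BASE - _RAM_MG_BASE * RAMUCIRUMAB_PRICE_PER_100MG / 100.0
) / _PAC_MG_BASE


DoseBasis = Literal["per_m2", "per_kg", "flat"]


@dataclass(frozen=True)
class RegimenComponent:
    drug: str
    basis: DoseBasis
    dose_mg: float            # per administration (per m2 / per kg / flat)
    administrations: int      # per 28-day cycle
    price_per_mg: float

    def __post_init__(self) -> None:
        if self.dose_mg < 0 or self.price_per_mg < 0 or self.administrations < 0:
            raise ValueError("doses, prices and administration counts must be >= 0")


@dataclass(frozen=True)
class RegimenDef:
    name: str
    components: tuple[RegimenComponent, ...]


def pr_regimen(
    ram_price_per_100mg: float = RAMUCIRUMAB_PRICE_PER_100MG,
    pac_price_per_mg: float = PACLITAXEL_PRICE_PER_MG,
) -> RegimenDef:
    """The maintenance paclitaxel + ramucirumab regimen definition."""
    return RegimenDef(
        name="paclitaxel+ramucirumab",
        components=(
            RegimenComponent("paclitaxel", "per_m2", 80.0, 3, pac_price_per_mg),
            RegimenComponent("ramucirumab", "per_kg", 8.0, 2, ram_price_per_100mg / 100.0),
        ),
    )


def cycle_drug_cost(regimen: RegimenDef, profile: PatientProfile) -> float:
    """USD per 28-day cycle for a regimen at a given patient profile."""
    total = 0.0
    for c in regimen.components:
        if c.basis == "per_m2":
            mult = profile.bsa
        elif c.basis == "per_kg":
            mult = profile.weight_kg
        elif c.basis == "flat":
            mult = 1.0
        else:
            raise ValueError(f"unknown dose basis {c.basis!r}")
        total += c.dose_mg * mult * c.administrations * c.price_per_mg
    return total


def pd_mix_cost(mix: Mapping[str, float], costs: Mapping[str, float]) -> float:
    """Weighted mean per-cycle cost of a post-progression regimen mix."""
    s = sum(mix.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"mix proportions sum to {s}, expected 1")
    return sum(p * costs[k] for k, p in mix.items())


AE_EVENTS = ("neutropenia", "anemia", "neuropathy", "vte")


# Published parameter table: name -> (mean, lower, upper, distribution, role)
PARAMETER_TABLE: dict[str, tuple[float, float, float, str, str]] = {
    "folfox_cost_cycle": (86.40, 64.80, 108.00, "gamma", "cost"),
    "ramucirumab_price_per_100mg": (616.05, 462.0375, 770.0625, "gamma", "cost"),
    "folfiri_cost_cycle": (149.83, 112.37, 187.29, "gamma", "cost"),
    "fu5_cost_cycle": (8.80, 6.60, 11.00, "gamma", "cost"),
    "tas102_cost_cycle": (552.68, 414.51, 690.85, "gamma", "cost"),
    "bsc_cost_cycle": (211.27, 158.45, 264.08, "gamma", "cost"),
    "lab_cost": (44.7, 33.52, 55.87, "gamma", "cost"),
    "imaging_cost": (95.45, 71.59, 119.31, "gamma", "cost"),
    "neutropenia_cost": (321.67, 241.25, 402.08, "gamma", "cost"),
    "anemia_cost": (472.73, 354.55, 590.91, "gamma", "cost"),
    "neuropathy_cost": (3000.0, 2250.0, 3750.0, "gamma", "cost"),
    "vte_cost": (9247.0, 6935.25, 11558.75, "gamma", "cost"),
    "eol_cost": (1419.15, 1064.37, 1773.94, "gamma", "cost"),
    "risk_neutropenia_tx": (0.26, 0.20, 0.32, "beta", "probability"),
    "risk_neutropenia_ctrl": (0.09, 0.068, 0.11, "beta", "probability"),
    "risk_anemia_tx": (0.02, 0.015, 0.025, "beta", "probability"),
    "risk_anemia_ctrl": (0.03, 0.02, 0.04, "beta", "probability"),
    "risk_neuropathy_tx": (0.06, 0.045, 0.075, "beta", "probability"),
    "risk_neuropathy_ctrl": (0.07, 0.0525, 0.0875, "beta", "probability"),
    "risk_vte_tx": (0.03, 0.0225, 0.0375, "beta", "probability"),
    "risk_vte_ctrl": (0.0, 0.0, 0.0, "beta", "probability"),
    "utility_pfs": (0.68, 0.51, 0.85, "beta", "utility"),
    "utility_pd": (0.42, 0.315, 0.525, "beta", "utility"),
    "disutility_neutropenia": (0.09, 0.0675, 0.1125, "beta", "utility"),
    "disutility_anemia": (0.125, 0.09375, 0.15625, "beta", "utility"),
    "disutility_neuropathy": (0.03, 0.02, 0.04, "beta", "utility"),
    "disutility_vte": (0.08, 0.06, 0.09, "beta", "utility"),
    "discount_rate": (0.05, 0.0, 0.08, "beta", "rate"),
    "mix_tx_folfiri": (0.36, 0.27, 0.45, "beta", "proportion"),
    "mix_tx_tas102": (0.17, 0.1275, 0.2125, "beta", "proportion"),
    "mix_tx_bsc": (0.29, 0.2175, 0.3625, "beta", "proportion"),
    "mix_tx_folfox": (0.18, 0.135, 0.225, "beta", "proportion"),
    "mix_ctrl_pr": (0.258, 0.1935, 0.3225, "beta", "proportion"),
    "mix_ctrl_folfiri": (0.112, 0.084, 0.14, "beta", "proportion"),
    "mix_ctrl_bsc": (0.63, 0.4725, 0.7875, "beta", "proportion"),
}


def default_values() -> dict[str, float]:
    return {k: v[0] for k, v in PARAMETER_TABLE.items()}


@dataclass(frozen=True)
class EconomicInputs:
    """Full economic parameter set plus dosing/scenario switches.

    ``values`` carries every published parameter (sampled or base);
    derived per-cycle costs are recomputed from the current values so
    sensitivity analyses can perturb any single entry.
    """

    values: dict[str, float] = field(default_factory=default_values)
    profile: PatientProfile = field(default_factory=PatientProfile)
    pap: bool = False
    ram_price_fraction: float = 1.0
    pac_price_per_mg: float = PACLITAXEL_PRICE_PER_MG

    def __post_init__(self) -> None:
        missing = set(PARAMETER_TABLE) - set(self.values)
        if missing:
            raise ValueError(f"missing economic parameters: {sorted(missing)}")
        if not (0.0 <= self.ram_price_fraction):
            raise ValueError("ram_price_fraction must be non-negative")
        for arm in ("tx", "ctrl"):
            s = sum(self.values[k] for k in self._mix_keys(arm))
            if abs(s - 1.0) > 1e-9 and not self._mix_perturbed:
                raise ValueError(f"{arm} post-progression mix sums to {s}")

    # mixes may be perturbed by sensitivity analyses; they are
    # renormalized inside pd_mix_cost_for_arm, so only construction-time
    # strictness is relaxed via this flag
    _mix_perturbed: bool = False

    @staticmethod
    def _mix_keys(arm: str) -> tuple[str, ...]:
        if arm == "tx":
            return ("mix_tx_folfiri", "mix_tx_tas102", "mix_tx_bsc", "mix_tx_folfox")
        return ("mix_ctrl_pr", "mix_ctrl_folfiri", "mix_ctrl_bsc")

    def with_values(self, **updates: float) -> "EconomicInputs":
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals, _mix_perturbed=True)

    # ------------------------------------------------------------------
    # derived costs

    @property
    def ram_price_nominal(self) -> float:
        """Scenario ramucirumab price per 100 mg (threshold fraction applied)."""
        return self.values["ramucirumab_price_per_100mg"] * self.ram_price_fraction

    @property
    def ram_price_effective(self) -> float:
        """Price per 100 mg paid during maintenance (PAP applied if on)."""
        return self.ram_price_nominal * (PAP_FACTOR if self.pap else 1.0)

    def pr_cycle_cost(self, on_treatment: bool) -> float:
        """Combination cost per cycle; the assistance program discounts
        only maintenance treatment, not post-progression use."""
        price = self.ram_price_effective if on_treatment else self.ram_price_nominal
        return cycle_drug_cost(pr_regimen(price, self.pac_price_per_mg), self.profile)

    def regimen_cycle_costs(self) -> dict[str, float]:
        return {
            "pr": self.pr_cycle_cost(on_treatment=False),
            "folfox": self.values["folfox_cost_cycle"],
            "folfiri": self.values["folfiri_cost_cycle"],
            "fu5": self.values["fu5_cost_cycle"],
            "tas102": self.values["tas102_cost_cycle"],
            "bsc": self.values["bsc_cost_cycle"],
        }

    def pd_mix(self, arm: str) -> dict[str, float]:
        key = "tx" if arm in ("tx", "treatment") else "ctrl"
        name_map = {
            "mix_tx_folfiri": "folfiri", "mix_tx_tas102": "tas102",
            "mix_tx_bsc": "bsc", "mix_tx_folfox": "folfox",
            "mix_ctrl_pr": "pr", "mix_ctrl_folfiri": "folfiri",
            "mix_ctrl_bsc": "bsc",
        }
        mix = {name_map[k]: self.values[k] for k in self._mix_keys(key)}
        s = sum(mix.values())
        if s <= 0:
            raise ValueError(f"{arm} mix proportions sum to {s}")
        return {k: v / s for k, v in mix.items()}

    def pd_mix_cost_for_arm(self, arm: str) -> float:
        return pd_mix_cost(self.pd_mix(arm), self.regimen_cycle_costs())

    @property
    def monitoring_cost_cycle(self) -> float:
        return self.values["lab_cost"] + self.values["imaging_cost"]

    def ae_burden(self, arm: str) -> tuple[float, float]:
        """One-off (cost USD, QALY loss) from grade >=3 adverse events.

        The disutility is applied for one cycle's duration.
        """
        suffix = "tx" if arm in ("tx", "treatment") else "ctrl"
        cost = qloss = 0.0
        for ev in AE_EVENTS:
            p = self.values[f"risk_{ev}_{suffix}"]
            cost += p * self.values[f"{ev}_cost"]
            qloss += p * self.values[f"disutility_{ev}"]
        return cost, qloss * CYCLE_YEARS

    @property
    def discount_rate(self) -> float:
        return self.values["discount_rate"]

    @property
    def utility_pfs(self) -> float:
        return min(self.values["utility_pfs"], 1.0)

    @property
    def utility_pd(self) -> float:
        return min(self.values["utility_pd"], 1.0)

    @property
    def eol_cost(self) -> float:
        return self.values["eol_cost"]


def apply_pap(inputs: EconomicInputs) -> EconomicInputs:
    """Turn on the buy-two-get-one-free assistance program (maintenance
    ramucirumab at 2/3 of nominal price; everything else unchanged)."""
    return replace(inputs, pap=True)


def ae_burden(inputs: EconomicInputs, arm: str) -> tuple[float, float]:
    return inputs.ae_burden(arm)
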