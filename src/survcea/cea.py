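"""Bind selected survival curves and economics into a runnable CEA model.

`CEAModel` precomputes the two cohort traces once (they depend only on
the survival functions, which sensitivity analyses hold fixed) and then
re-prices them cheaply for any perturbed economic inputs — the workhorse
behind the tornado, probabilistic and threshold analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

from .economics import EconomicInputs
from .markov import CEAResult, CohortTrace, ModelSettings, SurvFn, icer, run_cohort, accumulate


@dataclass
class CEAModel:
    s_pfs_tx: SurvFn
    s_os_tx: SurvFn
    s_pfs_ctrl: SurvFn
    s_os_ctrl: SurvFn
    econ: EconomicInputs
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self) -> None:
        self.trace_tx: CohortTrace = run_cohort(self.s_pfs_tx, self.s_os_tx, self.settings)
        self.trace_ctrl: CohortTrace = run_cohort(self.s_pfs_ctrl, self.s_os_ctrl, self.settings)

    def evaluate(self, econ: EconomicInputs | None = None) -> CEAResult:
        e = econ if econ is not None else self.econ
        tx = accumulate(self.trace_tx, e, self.settings, "treatment")
        ctrl = accumulate(self.trace_ctrl, e, self.settings, "control")
        return icer(tx, ctrl)

    def evaluate_with(self, **value_overrides: float) -> CEAResult:
        return self.evaluate(self.econ.with_values(**value_overrides))

    def evaluate_at_price_fraction(self, fraction: float) -> CEAResult:
        return self.evaluate(replace(self.econ, ram_price_fraction=fraction))

    def with_pap(self, pap: bool = True) -> "CEAModel":
        return CEAModel(self.s_pfs_tx, self.s_os_tx, self.s_pfs_ctrl,
                        self.s_os_ctrl, replace(self.econ, pap=pap), self.settings)
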