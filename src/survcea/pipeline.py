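"""End-to-end orchestration: reconstruct, fit, run, analyze, report.

A run reads digitized curve/risk CSVs (or generates the synthetic
fixture), reconstructs pseudo-IPD per arm and endpoint, fits the
survival zoo and selects extrapolation models by AIC, runs the Markov
cohort model, and produces the base case, tornado, probabilistic and
threshold analyses as machine-readable files plus a short text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import CEAModel
from .economics import EconomicInputs, PatientProfile, apply_pap
from .ipd import PseudoIPD, read_digitized_curve, reconstruct_ipd
from .markov import CEAResult, ModelSettings
from .survival import (FAMILIES, FitSettings, fit_all, information_table,
                       select_best, survival_at)
from .synthetic import make_fixture_study
from .uncertainty import (ceac, default_parameter_specs, owsa, psa,
                          threshold_price, tornado_frame)

logger = logging.getLogger(__name__)

ARMS = ("treatment", "control")
ENDPOINTS = ("PFS", "OS")


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline configuration."""

    data_dir: str | None = None        # directory of <arm>_<endpoint>_{curve,risk}.csv
    use_fixture: bool = True           # generate the synthetic study instead
    outdir: str = "results"
    seed: int = 20240601
    wtp: float = 40_457.32
    weight_loss: float = 0.10
    pap: bool = False
    half_cycle: bool = False
    monitoring_every_n_cycles: int = 1
    n_psa_draws: int = 1000
    make_plots: bool = False
    families: tuple[str, ...] = FAMILIES
    selection_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wtp <= 0:
            raise ValueError("WTP must be positive")
        if not (0.0 <= self.weight_loss <= 0.5):
            raise ValueError("weight_loss must lie in [0, 0.5]")

    def settings(self) -> ModelSettings:
        return ModelSettings(wtp=self.wtp, half_cycle_correction=self.half_cycle,
                             monitoring_every_n_cycles=self.monitoring_every_n_cycles)

    def econ(self) -> EconomicInputs:
        return EconomicInputs(profile=PatientProfile(weight_loss=self.weight_loss),
                              pap=self.pap)


def load_curves(config: RunConfig) -> dict:
    if config.use_fixture or config.data_dir is None:
        return make_fixture_study(seed=config.seed).curves
    curves = {}
    d = Path(config.data_dir)
    for arm in ARMS:
        for endpoint in ENDPOINTS:
            stem = f"{arm}_{endpoint.lower()}"
            curves[(arm, endpoint)] = read_digitized_curve(
                d / f"{stem}_curve.csv", d / f"{stem}_risk.csv",
                endpoint=endpoint, arm=arm,
            )
    return curves


def fit_and_select(ipd: PseudoIPD, config: RunConfig, key: str):
    fits = fit_all(ipd, FitSettings(seed=config.seed % 2**31),
                   families=config.families)
    table = information_table(fits)
    chosen = select_best(table, override=config.selection_overrides.get(key))
    fit = next(f for f in fits if f.family == chosen)
    return fit, table


def build_model(config: RunConfig) -> tuple[CEAModel, dict]:
    """Reconstruct, fit, select, and assemble the CEA model."""
    curves = load_curves(config)
    selections = {}
    surv = {}
    for (arm, endpoint), curve in curves.items():
        ipd = reconstruct_ipd(curve)
        key = f"{arm}_{endpoint.lower()}"
        fit, table = fit_and_select(ipd, config, key)
        selections[key] = {
            "family": fit.family,
            "n": ipd.n, "events": ipd.n_events,
            "aic": fit.aic, "bic": fit.bic,
            "table": table.drop(columns=["n"]).to_dict("records"),
        }
        surv[(arm, endpoint)] = fit
        logger.info("%s/%s: selected %s (AIC %.2f)", arm, endpoint, fit.family, fit.aic)
    model = CEAModel(
        s_pfs_tx=lambda t, f=surv[("treatment", "PFS")]: survival_at(f, t),
        s_os_tx=lambda t, f=surv[("treatment", "OS")]: survival_at(f, t),
        s_pfs_ctrl=lambda t, f=surv[("control", "PFS")]: survival_at(f, t),
        s_os_ctrl=lambda t, f=surv[("control", "OS")]: survival_at(f, t),
        econ=config.econ(), settings=config.settings(),
    )
    return model, selections


def _result_dict(res: CEAResult, wtp: float) -> dict:
    return {
        "cost_treatment": res.cost_treatment, "qalys_treatment": res.qalys_treatment,
        "cost_control": res.cost_control, "qalys_control": res.qalys_control,
        "delta_cost": res.delta_cost, "delta_effect": res.delta_effect,
        "icer": res.icer, "dominance": res.dominance, "verdict": res.verdict(wtp),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "build"
    try:
        model, selections = build_model(config)
        base = model.evaluate()

        stage = "owsa"
        tornado = tornado_frame(owsa(model))
        tornado.to_csv(out / "tornado.csv", index=False)

        stage = "psa"
        draws = psa(model, n_draws=config.n_psa_draws, seed=config.seed % 2**31)
        pd.DataFrame({"draw": np.arange(draws.n_draws),
                      "dcost": draws.delta_cost,
                      "dqaly": draws.delta_effect}).to_csv(
            out / "psa_draws.csv", index=False)
        grid = np.linspace(0.0, 4.0 * config.wtp, 81)
        pd.DataFrame(ceac(draws, grid), columns=["wtp", "p_ce"]).to_csv(
            out / "ceac.csv", index=False)

        stage = "threshold"
        thr = threshold_price(model, config.wtp)
        with open(out / "threshold.json", "w") as fh:
            json.dump(dataclasses.asdict(thr), fh, indent=2)

        if config.make_plots:
            stage = "plots"
            from . import plots
            entries = owsa(model)
            plots.tornado_plot(entries, base.icer, out / "tornado.png")
            plots.ce_scatter(draws, config.wtp, out / "ce_scatter.png")
            plots.ceac_plot(ceac(draws, grid), out / "ceac.png")
            fr = np.linspace(0, 1, 21)
            plots.threshold_plot(
                fr, np.array([model.evaluate_at_price_fraction(f).icer for f in fr]),
                config.wtp, out / "threshold.png")

        stage = "scenarios"
        pap_res = model.evaluate(apply_pap(model.econ))
        thr_pap = threshold_price(model.with_pap(), config.wtp)

        stage = "report"
        result = {
            "base_case": _result_dict(base, config.wtp),
            "pap_scenario": _result_dict(pap_res, config.wtp),
            "threshold": dataclasses.asdict(thr),
            "threshold_pap": dataclasses.asdict(thr_pap),
            "selections": {k: {kk: vv for kk, vv in v.items() if kk != "table"}
                           for k, v in selections.items()},
            "wtp": config.wtp,
        }
        with open(out / "result.json", "w") as fh:
            json.dump(result, fh, indent=2)
        for (arm, trace) in (("treatment", model.trace_tx), ("control", model.trace_ctrl)):
            df = pd.DataFrame(trace.occupancy, columns=["pfs", "pd", "death"])
            df.insert(0, "cycle", np.arange(len(df)))
            df["incident_deaths"] = np.concatenate([trace.incident_deaths, [np.nan]])
            df.to_csv(out / f"trace_{arm}.csv", index=False)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
                .encode()).hexdigest(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        summary = summarize(result)
        (out / "summary.txt").write_text(summary)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def summarize(result: dict) -> str:
    """Human-readable per-arm totals in the usual CEA table layout."""
    required = {"base_case", "wtp"}
    missing = required - set(result)
    if missing:
        raise ValueError(f"incomplete result bundle, missing {sorted(missing)}")
    lines = []
    wtp = result["wtp"]

    def block(title: str, r: dict) -> None:
        lines.append(title)
        lines.append(f"{'Group':<16}{'Total cost (USD)':>18}{'Effect (QALYs)':>16}"
                     f"{'Incr. cost':>14}{'Incr. effect':>14}{'ICER':>14}")
        icer_txt = ("dominant" if r["dominance"] == "dominant" else
                    "dominated" if r["dominance"] == "dominated" else
                    f"{r['icer']:,.2f}")
        lines.append(f"{'Treatment':<16}{r['cost_treatment']:>18,.2f}"
                     f"{r['qalys_treatment']:>16.2f}{r['delta_cost']:>14,.2f}"
                     f"{r['delta_effect']:>14.2f}{icer_txt:>14}")
        lines.append(f"{'Control':<16}{r['cost_control']:>18,.2f}"
                     f"{r['qalys_control']:>16.2f}{'-':>14}{'-':>14}{'-':>14}")
        lines.append(f"Verdict at WTP {wtp:,.2f} USD/QALY: {r['verdict']}")
        lines.append("")

    block("Base case", result["base_case"])
    if "pap_scenario" in result:
        block("Assistance-program scenario", result["pap_scenario"])
    thr = result.get("threshold")
    if thr and thr.get("fraction") is not None:
        lines.append(f"Threshold price: {100 * thr['fraction']:.0f}% of nominal "
                     f"({thr['price_per_100mg']:,.2f} USD/100 mg)")
    thr2 = result.get("threshold_pap")
    if thr2 and thr2.get("fraction") is not None:
        lines.append(f"Threshold price under assistance program: "
                     f"{100 * thr2['fraction']:.0f}% of nominal "
                     f"({thr2['price_per_100mg']:,.2f} USD/100 mg)")
    return "\n".join(lines) + "\n"


def load_econ_yaml(path: str | Path) -> EconomicInputs:
    """Read the economic parameter file (parameters / profile / scenario)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    prof = raw.get("profile", {})
    scen = raw.get("scenario", {})
    return EconomicInputs(
        values=dict(raw["parameters"]),
        profile=PatientProfile(
            reference_weight_kg=prof.get("reference_weight_kg", 66.9),
            height_cm=prof.get("height_cm", 163.5),
            weight_loss=prof.get("weight_loss", 0.10),
        ),
        pap=bool(scen.get("pap", False)),
        ram_price_fraction=float(scen.get("ram_price_fraction", 1.0)),
    )
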