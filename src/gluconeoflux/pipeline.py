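"""End-to-end orchestration: gate -> fit -> CIs -> cofactor ledger -> report.

A run is fully determined by its RunConfig (scenario or user files plus a
master seed); identical configs give byte-identical outputs.  Randomness
flows from the master seed through named substreams per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import synth
from .biomass import BiomassComposition, anabolic_cofactor_demand, biomass_efflux
from .cofactors import (CofactorParams, atp_accounting, attribute_to_pathways,
                        close_nadph, ledger_from_fluxes)
from .errors import GluconeofluxError
from .fit import (FluxEstimate, confidence_interval, fit,
                  gate_unlabeled_influx)

log = logging.getLogger("gluconeoflux.pipeline")


@dataclass
class RunConfig:
    scenario: str = "pputida_succinate_demo"
    out_dir: str = "run_out"
    seed: int = 7
    n_starts: int = 100
    sd_floor: float = 0.005
    po_ratio: float = 1.5
    mu: float = 0.85                  # h^-1, used for anabolic demand
    q_uptake: float = 12.0            # mmol gCDW^-1 h^-1, absolute scaling
    carryover_fraction: float = 0.0
    ci_reactions: tuple[str, ...] = ("PCK", "ICL", "ME")
    mid_noise_sd: float = 0.005


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "scenario"
    try:
        scen = synth.ScenarioConfig(seed=_stage_seed(config.seed, "data"),
                                    carryover_fraction=config.carryover_fraction,
                                    mid_noise_sd=config.mid_noise_sd,
                                    mu=config.mu)
        model, truth = synth.demo_truth(scen)
        measurements = synth.make_mid_dataset(model, truth, scen)
        gating = synth.make_gating_mids(model, truth, scen)

        stage = "gating"
        enabled = sorted(gate_unlabeled_influx(gating, model))
        log.info("enabled unlabeled influxes: %s", enabled or "none")

        stage = "fit"
        result = fit(model, measurements, synth.DEFAULT_TRACERS,
                     n_starts=config.n_starts,
                     seed=_stage_seed(config.seed, "fit"),
                     enabled_influxes=enabled, sd_floor=config.sd_floor)
        log.info("SSR %.3f (chi2 cutoff %.1f, dof %d, accepted=%s)",
                 result.ssr, result.chi2_cutoff_95, result.dof, result.accepted)

        stage = "confidence_intervals"
        cis = {}
        for rid in config.ci_reactions:
            if rid in model.reaction_ids:
                cis[rid] = confidence_interval(result, rid)

        stage = "cofactor_ledger"
        comp = BiomassComposition.from_yaml()
        demand = biomass_efflux(config.mu, comp)
        cof_demand = anabolic_cofactor_demand(demand, comp, config.mu)
        abs_fluxes = result.best_fluxes.to_absolute(config.q_uptake)
        scale = config.q_uptake / 100.0
        entries = {}
        for rid, v in abs_fluxes.values.items():
            if rid in cis:
                c = cis[rid]
                entries[rid] = FluxEstimate(rid, v, c.lb95 * scale,
                                            c.ub95 * scale, c.flags)
            else:
                entries[rid] = v
        ledger = ledger_from_fluxes(entries, model, cof_demand,
                                    CofactorParams(config.po_ratio))
        close_nadph(ledger)
        atp_accounting(ledger, CofactorParams(config.po_ratio))
        attribute_to_pathways(ledger, abs_fluxes, model)
    except GluconeofluxError as exc:
        raise GluconeofluxError(f"pipeline stage {stage!r} failed: {exc}") from exc

    fit_json = {
        "seed": config.seed,
        "scenario": config.scenario,
        "enabled_influxes": enabled,
        "fluxes_pct_uptake": {k: round(v, 6)
                              for k, v in result.best_fluxes.values.items()},
        "exchange_fluxes": {k: round(v, 6)
                            for k, v in result.best_fluxes.exchange_values.items()},
        "ssr": round(result.ssr, 6),
        "dof": result.dof,
        "chi2_cutoff_95": round(result.chi2_cutoff_95, 4),
        "accepted": result.accepted,
        "confidence_intervals": {
            rid: {"value": round(c.value, 4), "lb95": round(c.lb95, 4),
                  "ub95": round(c.ub95, 4), "sd": round(c.sd, 4),
                  "flags": list(c.flags)}
            for rid, c in cis.items()},
    }
    ledger_json = {
        "units": "mmol_gCDW-1_h-1",
        "q_uptake": config.q_uptake,
        "po_ratio": config.po_ratio,
        "production": {k: round(v, 4) for k, v in ledger.production.items()},
        "consumption": {k: round(v, 4) for k, v in ledger.consumption.items()},
        "production_sd": {k: round(v, 4) for k, v in ledger.production_sd.items()},
        "transhydrogenase_flux": round(ledger.transhydrogenase_flux, 4),
        "fraction_nadph_from_thd": round(ledger.fraction_nadph_from_thd, 4),
        "oxphos_atp": round(ledger.oxphos_atp, 4),
        "substrate_level_atp": round(ledger.substrate_level_atp, 4),
        "atp_surplus": round(ledger.atp_surplus, 4),
        "attribution": {c: {p: round(f, 4) for p, f in t.items()}
                        for c, t in ledger.attribution.items()},
        "flags": ledger.flags,
    }
    (out / "fit.json").write_text(json.dumps(fit_json, indent=1, sort_keys=True))
    (out / "ledger.json").write_text(json.dumps(ledger_json, indent=1, sort_keys=True))

    lines = [
        f"# gluconeoflux run: {config.scenario} (seed {config.seed})", "",
        f"chi-square verdict: SSR {result.ssr:.2f} vs cutoff "
        f"{result.chi2_cutoff_95:.1f} (dof {result.dof}) -> "
        f"{'accepted' if result.accepted else 'REJECTED'}", "",
        "| reaction | flux (% uptake) | LB95 | UB95 | SD |",
        "|---|---|---|---|---|",
    ]
    for rid, c in cis.items():
        lines.append(f"| {rid} | {c.value:.2f} | {c.lb95:.2f} | {c.ub95:.2f} "
                     f"| {c.sd:.2f} |")
    lines += [
        "",
        f"NADPH from transhydrogenase: {100 * ledger.fraction_nadph_from_thd:.0f}%",
        f"oxphos ATP: {ledger.oxphos_atp:.2f}; substrate-level ATP: "
        f"{ledger.substrate_level_atp:.2f}; ATP surplus: {ledger.atp_surplus:.2f} "
        "(mmol gCDW-1 h-1)",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return {"fit": fit_json, "ledger": ledger_json, "result": result,
            "cis": cis, "model": model, "truth": truth}


def compare_runs(run_a: dict | str, run_b: dict | str, flux_ids) -> dict:
    """Per-flux precision scores with run_a as 'unwashed', run_b as 'washed'.

    Accepts run report dicts from :func:`run_pipeline` or run directories
    containing fit.json.  Missing CIs yield None with a warning.
    """
    def load(run):
        if isinstance(run, (str, Path)):
            return json.loads((Path(run) / "fit.json").read_text())
        return run["fit"]

    a, b = load(run_a), load(run_b)
    out = {}
    for rid in flux_ids:
        ca = a["confidence_intervals"].get(rid)
        cb = b["confidence_intervals"].get(rid)
        if ca is None or cb is None:
            log.warning("no CI for %s in one of the runs", rid)
            out[rid] = None
            continue
        wa = ca["ub95"] - ca["lb95"]
        wb = cb["ub95"] - cb["lb95"]
        out[rid] = float("inf") if wb == 0 else (wa / wb) ** 2
    return out
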