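"""Synthetic data generation for every pipeline stage.

The default scenario (``pputida_succinate_demo``) emulates the study
conditions for gluconeogenic growth on succinate: parallel labeling with
[1,4-13C4]- and [2,3-13C4]-succinate, three replicates per tracer (six
isotopomer data sets in total), Gaussian noise of SD 0.005 on
mass-isotopomer fractions, optional unlabeled carry-over influx below 7%
of uptake, exponential growth with a lag phase, and a two-condition
proteome with known differential proteins.  Truth values are returned
alongside each dataset so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cofactors import AdenylatePools
from .data import load_bundled_model
from .emu import simulate_metabolites
from .errors import GluconeofluxError, InfeasibleError
from .fit import FitProblem, MeasurementSet, MIDMeasurement, RateMeasurement
from .mid import TracerSpec
from .network import FluxVector, NetworkModel

#: tracer pair used in the parallel labeling design
DEFAULT_TRACERS = {
    "suc_14": TracerSpec("SUC", [("1001", 1.0)], purity=0.99),
    "suc_23": TracerSpec("SUC", [("0110", 1.0)], purity=0.99),
}
UNIFORM_TRACER = TracerSpec("SUC", [("1111", 1.0)], purity=0.99)

DEMO_MEASURED_FRAGMENTS = ("MAL", "FUM", "CIT", "AKG", "PEP", "PG3", "DHAP", "G6P")

#: demo ground truth, % of succinate uptake (uptake = 100); high TCA flux,
#: ~21% gluconeogenic flux from PEP, inactive glyoxylate shunt
DEMO_TRUE_FLUXES = {
    "UPT": 100.0, "SDH": 126.0, "FUMA": 126.0, "MDH": 70.0, "CS": 34.0,
    "ICD": 34.0, "AKGX": 26.0, "ICL": 0.0, "MS": 0.0, "PCK": 21.0,
    "ME": 56.0, "PDH": 46.0, "ENO": 21.0, "TRI": 16.0, "TPI": 8.0,
    "HEX": 8.0, "PGI": 8.0, "CO2_OUT": 183.0, "MAL_IN": 0.0,
    "BM_OAA": 15.0, "BM_AKG": 8.0, "BM_PYR": 10.0, "BM_ACCOA": 12.0,
    "BM_PG3": 5.0, "BM_G6P": 8.0,
}
DEMO_RATE_MEASURED = ("BM_OAA", "BM_AKG", "BM_PYR", "BM_ACCOA", "BM_PG3", "BM_G6P")


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    species_tag: str = "pputida_succinate_demo"
    replicates: int = 3
    mid_noise_sd: float = 0.005
    rate_sd: float = 1.0            # SD attached to rate measurements (% uptake)
    rate_noise_sd: float = 1.0      # noise actually added to rate values
    carryover_fraction: float = 0.0  # unlabeled influx as fraction of uptake
    carryover_metabolite: str = "MAL"
    mu: float = 0.85                # h^-1
    lag: float = 2.0                # h
    od_noise: float = 0.02          # multiplicative lognormal sigma
    od0: float = 0.05
    od_to_cdw: float = 0.4          # gCDW L^-1 per OD unit
    substrate_conc0: float = 25.0   # mM (100 mM carbon for succinate)
    yield_x_s: float = 0.06         # gCDW per mmol substrate
    secretion_carbon_fraction: float = 0.0
    secretion_carbons: int = 6
    substrate_carbons: int = 4
    n_proteins: int = 1000
    frac_differential: float = 0.1
    z_effect: float = 4.0           # true shift in units of (u1 + u2)
    rep_sd: float = 0.25            # log2 replicate SD
    within_se: float = 0.25         # within-replicate SE (log2)
    proteome_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mid_noise_sd < 0 or self.od_noise < 0 or self.rep_sd < 0:
            raise GluconeofluxError("noise SDs must be >= 0")
        if self.mid_noise_sd > 0.25:
            raise GluconeofluxError(
                "MID noise SD above 0.25 degenerates truncation/renormalization")
        if not 0.0 <= self.carryover_fraction <= 0.5:
            raise GluconeofluxError("carryover fraction must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# flux truths

def _polytope(model: NetworkModel, uptake_value: float = 100.0,
              enabled_influxes=(), fixed_fluxes=None) -> FitProblem:
    return FitProblem(model, MeasurementSet([], []), {},
                      uptake_value=uptake_value,
                      enabled_influxes=enabled_influxes,
                      fixed_fluxes=fixed_fluxes)


def sample_true_fluxes(model: NetworkModel, seed: int = 0,
                       uptake_value: float = 100.0, enabled_influxes=(),
                       exchange_range: tuple[float, float] = (0.0, 0.0),
                       n: int = 1) -> FluxVector | list[FluxVector]:
    """Seeded feasible flux draws (uptake fixed, S v = 0, signs respected)."""
    rng = np.random.default_rng(seed)
    prob = _polytope(model, uptake_value, enabled_influxes)
    us = prob.sample_feasible(rng, n)
    out = []
    for u in us:
        v = prob.v0 + (prob.N @ u if prob.k else 0.0)
        xch = {rid: float(rng.uniform(*exchange_range))
               for rid in prob.xch_rids}
        out.append(FluxVector(dict(zip(prob.rids, v)), xch))
    return out[0] if n == 1 else out


def project_to_feasible(model: NetworkModel, target: FluxVector,
                        uptake_value: float = 100.0, enabled_influxes=(),
                        fixed_fluxes=None) -> FluxVector:
    """Closest (least-squares) steady-state flux vector to ``target``."""
    prob = _polytope(model, uptake_value, enabled_influxes, fixed_fluxes)
    vt = target.as_array(model)
    if prob.k == 0:
        u = np.zeros(0)
    else:
        u, *_ = np.linalg.lstsq(prob.N, vt - prob.v0, rcond=None)
    v = prob.v0 + (prob.N @ u if prob.k else 0.0)
    viol = prob._violations(v)
    if viol.size and viol.min() < -1e-9 and prob.k:
        # sign constraints bind: constrained projection instead
        from scipy.optimize import minimize
        Gu = prob.G @ prob.N
        hu = prob.h - prob.G @ prob.v0
        res = minimize(
            lambda uu: float(np.sum((prob.v0 + prob.N @ uu - vt) ** 2)),
            u, method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda uu: Gu @ uu - hu}],
            options={"maxiter": 500, "ftol": 1e-12})
        v = prob.v0 + prob.N @ res.x
        viol = prob._violations(v)
        if viol.size and viol.min() < -1e-6:
            raise InfeasibleError("no feasible projection of the target fluxes")
        v = np.where(np.abs(v) < 1e-10, 0.0, v)
    return FluxVector(dict(zip(prob.rids, v)), dict(target.exchange_values))


def demo_truth(config: ScenarioConfig | None = None) -> tuple[NetworkModel, FluxVector]:
    """Demo model plus its ground-truth fluxes (with carry-over if configured)."""
    config = config or ScenarioConfig()
    model = load_bundled_model("pputida_succinate_demo")
    truth = FluxVector(dict(DEMO_TRUE_FLUXES))
    if config.carryover_fraction > 0:
        f = config.carryover_fraction * 100.0
        target = FluxVector({**DEMO_TRUE_FLUXES, "MAL_IN": f})
        truth = project_to_feasible(model, target,
                                    enabled_influxes=("MAL_IN",),
                                    fixed_fluxes={"MAL_IN": f})
    return model, truth


# ---------------------------------------------------------------------------
# MID datasets

def _noisy_mid(rng: np.random.Generator, fractions: np.ndarray,
               sd: float) -> np.ndarray:
    if sd == 0:
        return fractions.copy()
    for _ in range(100):
        noisy = fractions + rng.normal(0.0, sd, size=fractions.shape)
        noisy = np.clip(noisy, 0.0, None)  # truncate below zero
        total = noisy.sum()
        if total > 0.1:
            return noisy / total
    raise GluconeofluxError("MID noise too large: renormalization degenerates")


def make_mid_dataset(model: NetworkModel, fluxes: FluxVector,
                     config: ScenarioConfig,
                     tracers: dict[str, TracerSpec] | None = None,
                     fragments=DEMO_MEASURED_FRAGMENTS,
                     rate_reactions=DEMO_RATE_MEASURED,
                     seed: int | None = None) -> MeasurementSet:
    """Parallel-tracer measurement set: simulate, add truncated-Gaussian
    noise, renormalize, attach SDs; plus rate measurements for the drains."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tracers = tracers or DEFAULT_TRACERS
    mids: list[MIDMeasurement] = []
    for tid in sorted(tracers):
        sims = simulate_metabolites(model, fluxes, tracers[tid], fragments)
        for rep in range(1, config.replicates + 1):
            for frag in fragments:
                clean = sims[frag].fractions
                noisy = _noisy_mid(rng, clean, config.mid_noise_sd)
                sd = np.full_like(noisy, max(config.mid_noise_sd, 1e-6))
                mids.append(MIDMeasurement(tid, rep, frag, noisy, sd))
    rates = []
    for rid in rate_reactions:
        truth = fluxes.values[rid]
        value = truth + rng.normal(0.0, config.rate_noise_sd) \
            if config.rate_noise_sd > 0 else truth
        rates.append(RateMeasurement(rid, float(value), config.rate_sd))
    return MeasurementSet(mids, rates)


def make_gating_mids(model: NetworkModel, fluxes: FluxVector,
                     config: ScenarioConfig, fragments=DEMO_MEASURED_FRAGMENTS,
                     seed: int | None = None) -> list[MIDMeasurement]:
    """Fully-labeled ([U-13C4]) tracer experiment used for influx gating."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    sims = simulate_metabolites(model, fluxes, UNIFORM_TRACER, fragments)
    out = []
    for rep in range(1, config.replicates + 1):
        for frag in fragments:
            noisy = _noisy_mid(rng, sims[frag].fractions, config.mid_noise_sd)
            sd = np.full_like(noisy, max(config.mid_noise_sd, 1e-6))
            out.append(MIDMeasurement("suc_U", rep, frag, noisy, sd))
    return out


# ---------------------------------------------------------------------------
# physiology

def make_physiology_dataset(config: ScenarioConfig, seed: int | None = None,
                            t_end: float = 12.0, n_points: int = 25) -> dict:
    """OD and concentration time courses for exponential growth with lag.

    Substrate falls linearly with biomass at slope -1/Y_X/S; an optional
    secreted product rises so that its carbon flux is the configured
    fraction of carbon uptake.
    """
    if config.mu <= 0:
        raise GluconeofluxError("mu must be > 0")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 13)
    t = np.linspace(0.0, t_end, n_points)
    od_clean = np.where(t < config.lag, config.od0,
                        config.od0 * np.exp(config.mu * (t - config.lag)))
    noise = rng.lognormal(0.0, config.od_noise, size=t.shape) if config.od_noise else 1.0
    od = od_clean * noise
    cdw = od_clean * config.od_to_cdw          # gCDW per liter
    x0 = cdw[0]
    sub_slope = -1.0 / config.yield_x_s        # mmol substrate per gCDW
    substrate = config.substrate_conc0 + (cdw - x0) * sub_slope
    conc = {"substrate": (t, np.clip(substrate, 0.0, None))}
    truth = {"mu": config.mu, "lag": config.lag,
             "q_substrate": config.mu / config.yield_x_s,
             "od_to_cdw": config.od_to_cdw}
    if config.secretion_carbon_fraction > 0:
        prod_slope = (config.secretion_carbon_fraction / config.yield_x_s
                      * config.substrate_carbons / config.secretion_carbons)
        product = (cdw - x0) * prod_slope
        conc["product"] = (t, product)
        truth["q_product"] = config.mu * prod_slope
    return {"time": t, "od": od, "cdw": (t, cdw), "conc": conc, "truth": truth}


# ---------------------------------------------------------------------------
# proteome

def make_proteome(config: ScenarioConfig, seed: int | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition log2 proteome with known differential proteins.

    Returns (replicate-level table, truth table with the applied shifts).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 29)
    n = config.n_proteins
    n_diff = int(round(config.frac_differential * n))
    u_cond = float(np.hypot(config.rep_sd, config.within_se))
    shift_mag = config.z_effect * 2 * u_cond
    base = rng.normal(20.0, 2.0, size=n)
    is_diff = np.zeros(n, dtype=bool)
    is_diff[:n_diff] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    shifts = np.where(is_diff, signs * shift_mag, 0.0)
    rows = []
    for i in range(n):
        name = f"P{i:04d}"
        for cond, mean in (("succinate", base[i] + shifts[i]),
                           ("gluconate", base[i])):
            for rep in range(1, config.proteome_replicates + 1):
                rows.append({
                    "protein": name, "condition": cond, "replicate": rep,
                    "log2_abundance": float(mean + rng.normal(0, config.rep_sd)),
                    "within_se": float(abs(rng.normal(config.within_se,
                                                      0.1 * config.within_se))),
                })
    table = pd.DataFrame(rows)
    truth = pd.DataFrame({"protein": [f"P{i:04d}" for i in range(n)],
                          "differential": is_diff, "shift": shifts})
    return table, truth


# ---------------------------------------------------------------------------
# adenylate pools

def make_adenylate_pools(target_ec: float, total: float = 10.0,
                         adp_share: float | None = None) -> AdenylatePools:
    """Pools whose energy charge equals ``target_ec`` exactly.

    The ADP share d is a free parameter subject to d <= 2*EC and
    d <= 2*(1-EC); the default picks d = min(0.3, those caps).
    """
    if not 0.0 <= target_ec <= 1.0:
        raise GluconeofluxError(f"energy charge must be in [0, 1], got {target_ec}")
    cap = min(2 * target_ec, 2 * (1 - target_ec))
    d = min(0.3, cap) if adp_share is None else adp_share
    if d > cap + 1e-12:
        raise GluconeofluxError(f"ADP share {d} incompatible with EC {target_ec}")
    a = target_ec - d / 2
    m = 1.0 - a - d
    return AdenylatePools(atp=a * total, adp=d * total,
                          amp=max(m, 0.0) * total)
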