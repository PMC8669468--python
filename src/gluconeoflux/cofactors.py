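"""Cofactor and ATP accounting from an optimized flux distribution.

Reaction-level cofactor stoichiometry (NADH and ubiquinol lumped as one
respiratory pool, NADPH, ATP) is summed over the absolute fluxes to give
production and consumption rates in mmol gCDW^-1 h^-1.  The anabolic
NADPH deficit is closed by transhydrogenase conversion of NADH to NADPH;
oxidative phosphorylation then converts the remaining respirable
NADH/UQH2 to ATP at a P/O ratio (default 1.5), and the ATP surplus -
total production minus anabolic plus reaction-level consumption - absorbs
maintenance and unmodeled processes.  Uncertainty is propagated as the
root-sum-of-squares of the contributing flux SDs (flux correlations
ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .biomass import PATHWAYS  # noqa: F401  (re-exported for callers)
from .errors import ConfigurationError, UnitError
from .fit import FluxEstimate
from .network import COFACTOR_KEYS, FluxVector, NetworkModel

COFACTORS = ("NADH_UQH2", "NADPH", "ATP")
_KEY_MAP = dict(zip(COFACTOR_KEYS, COFACTORS))


@dataclass
class CofactorParams:
    po_ratio: float = 1.5  # mol ATP per mol NADH/UQH2 oxidized

    def __post_init__(self) -> None:
        if self.po_ratio <= 0:
            raise ValueError(f"P/O ratio must be > 0, got {self.po_ratio}")


@dataclass
class AdenylatePools:
    atp: float
    adp: float
    amp: float

    def __post_init__(self) -> None:
        if min(self.atp, self.adp, self.amp) < 0:
            raise ValueError("adenylate pools must be >= 0")


def energy_charge(pools: AdenylatePools) -> float:
    """Adenylate energy charge ([ATP] + 0.5 [ADP]) / ([ATP]+[ADP]+[AMP])."""
    total = pools.atp + pools.adp + pools.amp
    if total <= 0:
        raise ValueError("all adenylate pools are zero")
    return (pools.atp + 0.5 * pools.adp) / total


@dataclass
class CofactorLedger:
    production: dict[str, float]
    consumption: dict[str, float]
    production_sd: dict[str, float] = field(default_factory=dict)
    consumption_sd: dict[str, float] = field(default_factory=dict)
    anabolic_demand: dict[str, float] = field(default_factory=dict)
    transhydrogenase_flux: float = 0.0
    fraction_nadph_from_thd: float = 0.0
    oxphos_atp: float = 0.0
    substrate_level_atp: float = 0.0
    atp_surplus: float = 0.0
    attribution: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    closed: bool = False

    def balance(self, cofactor: str) -> float:
        return self.production[cofactor] - self.consumption[cofactor]


def _flux_value_and_sd(entry) -> tuple[float, float]:
    if isinstance(entry, FluxEstimate):
        return entry.value, entry.sd
    return float(entry), 0.0


def ledger_from_fluxes(fluxes, model: NetworkModel,
                       anabolic_demand: dict[str, float] | None = None,
                       params: CofactorParams | None = None) -> CofactorLedger:
    """Reaction-level cofactor production/consumption rates.

    ``fluxes`` is a FluxVector in absolute units (mmol gCDW^-1 h^-1) or a
    dict mapping reaction id to FluxEstimate (absolute units) so SDs
    propagate.  ``anabolic_demand`` adds biosynthetic consumption per
    cofactor.  Call :func:`close_nadph` and :func:`atp_accounting` next.
    """
    if isinstance(fluxes, FluxVector):
        if fluxes.units != "absolute":
            raise UnitError(
                "cofactor ledger requires absolute fluxes "
                "(FluxVector.to_absolute(q_uptake)); got normalized units")
        entries = dict(fluxes.values)
    else:
        entries = dict(fluxes)
    demand = dict(anabolic_demand or {})
    production = {c: 0.0 for c in COFACTORS}
    consumption = {c: 0.0 for c in COFACTORS}
    prod_var = {c: 0.0 for c in COFACTORS}
    cons_var = {c: 0.0 for c in COFACTORS}
    for r in model.reactions:
        if r.id not in entries:
            continue
        v, sd = _flux_value_and_sd(entries[r.id])
        for key, delta in r.cofactor_deltas.items():
            cof = _KEY_MAP[key]
            rate = v * delta
            if rate >= 0:
                production[cof] += rate
                prod_var[cof] += (sd * delta) ** 2
            else:
                consumption[cof] += -rate
                cons_var[cof] += (sd * delta) ** 2
    for cof in COFACTORS:
        consumption[cof] += demand.get(cof, 0.0)
    return CofactorLedger(
        production=production,
        consumption=consumption,
        production_sd={c: math.sqrt(v) for c, v in prod_var.items()},
        consumption_sd={c: math.sqrt(v) for c, v in cons_var.items()},
        anabolic_demand=demand,
    )


def close_nadph(ledger: CofactorLedger) -> CofactorLedger:
    """Supply the anabolic NADPH deficit by transhydrogenase (NADH -> NADPH).

    After closure NADPH production equals consumption exactly; the
    transhydrogenase flux debits the NADH/UQH2 pool one-for-one.
    """
    deficit = ledger.consumption["NADPH"] - ledger.production["NADPH"]
    thd = max(0.0, deficit)
    ledger.transhydrogenase_flux = thd
    ledger.production["NADPH"] += thd
    ledger.consumption["NADH_UQH2"] += thd
    if thd > 0:
        # force the closure identity to be exact
        ledger.production["NADPH"] = ledger.consumption["NADPH"]
    total_nadph = ledger.production["NADPH"]
    ledger.fraction_nadph_from_thd = thd / total_nadph if total_nadph > 0 else 0.0
    ledger.closed = True
    return ledger


def atp_accounting(ledger: CofactorLedger,
                   params: CofactorParams | None = None) -> CofactorLedger:
    """Oxidative-phosphorylation ATP and the ATP surplus.

    Respirable NADH/UQH2 = production - transhydrogenase flux -
    non-respiratory reaction consumption; oxphos ATP = P/O x respirable.
    Surplus = total ATP production - total ATP consumption (anabolic
    demand plus reaction-level costs), i.e. maintenance and everything
    not modeled.
    """
    if not ledger.closed:
        raise ConfigurationError("close_nadph must run before atp_accounting")
    params = params or CofactorParams()
    respirable = ledger.production["NADH_UQH2"] - ledger.consumption["NADH_UQH2"]
    if respirable < 0:
        ledger.flags.append("negative_respirable_nadh")
        respirable = 0.0
    ledger.oxphos_atp = params.po_ratio * respirable
    ledger.substrate_level_atp = ledger.production["ATP"]
    ledger.production["ATP"] = ledger.substrate_level_atp + ledger.oxphos_atp
    ledger.atp_surplus = ledger.production["ATP"] - ledger.consumption["ATP"]
    if ledger.atp_surplus < 0:
        ledger.flags.append("negative_atp_surplus")
    return ledger


def attribute_to_pathways(ledger: CofactorLedger, fluxes, model: NetworkModel
                          ) -> dict[str, dict[str, float]]:
    """Fraction of each cofactor's production per pathway tag.

    Transhydrogenase-derived NADPH is attributed to the pathways of the
    NADH it consumed (proportional to NADH production shares), and
    oxidative-phosphorylation ATP likewise follows the NADH/UQH2 origin.
    """
    if isinstance(fluxes, FluxVector):
        entries = {rid: v for rid, v in fluxes.values.items()}
    else:
        entries = {rid: _flux_value_and_sd(e)[0] for rid, e in fluxes.items()}
    by_pathway: dict[str, dict[str, float]] = {c: {} for c in COFACTORS}
    for r in model.reactions:
        if r.id not in entries:
            continue
        v = entries[r.id]
        for key, delta in r.cofactor_deltas.items():
            rate = v * delta
            if rate <= 0:
                continue
            if not r.pathway:
                raise ConfigurationError(
                    f"reaction {r.id} produces {key} but has no pathway tag")
            cof = _KEY_MAP[key]
            by_pathway[cof][r.pathway] = by_pathway[cof].get(r.pathway, 0.0) + rate

    nadh_total = sum(by_pathway["NADH_UQH2"].values())
    nadh_shares = ({p: v / nadh_total for p, v in by_pathway["NADH_UQH2"].items()}
                   if nadh_total > 0 else {})
    if ledger.transhydrogenase_flux > 0:
        for p, share in nadh_shares.items():
            by_pathway["NADPH"][p] = (by_pathway["NADPH"].get(p, 0.0)
                                      + share * ledger.transhydrogenase_flux)
    if ledger.oxphos_atp > 0:
        for p, share in nadh_shares.items():
            by_pathway["ATP"][p] = (by_pathway["ATP"].get(p, 0.0)
                                    + share * ledger.oxphos_atp)
    out: dict[str, dict[str, float]] = {}
    for cof, table in by_pathway.items():
        total = sum(table.values())
        out[cof] = ({p: v / total for p, v in table.items()} if total > 0 else {})
    ledger.attribution = out
    return out
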