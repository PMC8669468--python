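"""Biomass demand: precursor effluxes, pathway partitioning, cofactor cost.

The biosynthetic drain on central metabolism is growth rate times the
macromolecular composition: for each precursor p,

    r_p = mu * sum_components  mass_fraction_c * stoich_{c,p}

in mmol gCDW^-1 h^-1.  Demand is partitioned between the TCA cycle, the
PP pathway and the EMP pathway on a carbon basis (rate times precursor
carbon number), and the anabolic cofactor bill adds a polymerization ATP
term per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .data import composition_path

PATHWAYS = ("TCA", "PP", "EMP")


@dataclass
class BiomassComposition:
    mass_fractions: dict[str, float]
    precursor_stoichiometry: dict[str, dict[str, float]]  # component -> precursor -> mmol/g
    polymerization_atp: dict[str, float]                   # component -> ATP per monomer
    monomers_per_g: dict[str, float]                       # component -> mmol monomer per g
    cofactor_demand_per_precursor: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_assignment: dict[str, str] = field(default_factory=dict)
    carbon_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if any(f < 0 for f in self.mass_fractions.values()) or total > 1 + 1e-9:
            raise ConfigurationError(
                f"mass fractions must be >= 0 and sum to <= 1 (sum={total:.3f})")
        for comp, table in self.precursor_stoichiometry.items():
            if any(v < 0 for v in table.values()):
                raise ConfigurationError(f"negative stoichiometry in {comp}")

    @classmethod
    def from_yaml(cls, path=None) -> "BiomassComposition":
        path = path or composition_path()
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            mass_fractions=raw["mass_fractions"],
            precursor_stoichiometry=raw["precursor_stoichiometry"],
            polymerization_atp=raw["polymerization_atp"],
            monomers_per_g=raw["monomers_per_g"],
            cofactor_demand_per_precursor=raw.get("cofactor_demand_per_precursor", {}),
            pathway_assignment=raw.get("pathway_assignment", {}),
            carbon_counts=raw.get("carbon_counts", {}),
        )


@dataclass
class PrecursorDemand:
    rates: dict[str, float]                 # precursor -> mmol gCDW^-1 h^-1
    pathway_assignment: dict[str, str]
    carbon_counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(r < -1e-12 for r in self.rates.values()):
            raise ConfigurationError("negative precursor demand rate")


def biomass_efflux(growth_rate: float, composition: BiomassComposition) -> PrecursorDemand:
    """Precursor efflux rates at growth rate ``growth_rate`` (h^-1)."""
    if growth_rate < 0:
        raise ValueError(f"growth rate must be >= 0, got {growth_rate}")
    rates: dict[str, float] = {}
    for comp, frac in composition.mass_fractions.items():
        for prec, stoich in composition.precursor_stoichiometry.get(comp, {}).items():
            rates[prec] = rates.get(prec, 0.0) + growth_rate * frac * stoich
    return PrecursorDemand(rates, dict(composition.pathway_assignment),
                           dict(composition.carbon_counts))


def pathway_partition(demand: PrecursorDemand) -> dict[str, float]:
    """Fraction of total carbon efflux supplied by each pathway."""
    carbon_rates: dict[str, float] = {p: 0.0 for p in PATHWAYS}
    total = 0.0
    for prec, rate in demand.rates.items():
        pathway = demand.pathway_assignment.get(prec)
        if pathway is None:
            raise ConfigurationError(f"precursor {prec} has no pathway assignment")
        carbons = demand.carbon_counts.get(prec)
        if carbons is None:
            raise ConfigurationError(f"precursor {prec} has no carbon count")
        c_rate = rate * carbons
        carbon_rates[pathway] = carbon_rates.get(pathway, 0.0) + c_rate
        total += c_rate
    if total <= 0:
        return {p: 0.0 for p in carbon_rates}
    return {p: r / total for p, r in carbon_rates.items()}


def anabolic_cofactor_demand(demand: PrecursorDemand,
                             composition: BiomassComposition,
                             growth_rate: float) -> dict[str, float]:
    """Cofactor consumption (mmol gCDW^-1 h^-1) for anabolism.

    Per-precursor costs scale with the precursor efflux; the ATP bill adds
    the polymerization term mu * sum_c fraction_c * monomers_c * atp_c.
    """
    if not composition.cofactor_demand_per_precursor:
        raise ConfigurationError("cofactor demand table not configured")
    out: dict[str, float] = {}
    for cof, table in composition.cofactor_demand_per_precursor.items():
        out[cof] = sum(demand.rates.get(prec, 0.0) * coef
                       for prec, coef in table.items())
    poly = sum(composition.mass_fractions.get(c, 0.0)
               * composition.monomers_per_g.get(c, 0.0)
               * composition.polymerization_atp.get(c, 0.0)
               for c in composition.mass_fractions) * growth_rate
    out["ATP"] = out.get("ATP", 0.0) + poly
    out.setdefault("NADPH", 0.0)
    out.setdefault("NADH_UQH2", 0.0)
    return out
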