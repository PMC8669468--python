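"""Cofactor and ATP accounting with transhydrogenase closure.

Scales the benchmark flux map to an absolute succinate uptake of
12 mmol gCDW^-1 h^-1, adds the anabolic cofactor demand at mu = 0.85 h^-1
from the default biomass composition, closes the NADPH deficit with
transhydrogenase and converts respirable NADH/UQH2 to ATP at P/O = 1.5.
The printed ledger mirrors the production/consumption bar-chart style of
flux papers: without an oxidative PP pathway, a large share of NADPH must
come from NADH via transhydrogenase, and the TCA cycle dominates all
three pools.
"""

import gluconeoflux as gf
from gluconeoflux import synth
from gluconeoflux.biomass import (BiomassComposition,
                                  anabolic_cofactor_demand, biomass_efflux)

mu, q_uptake = 0.85, 12.0
model, truth = synth.demo_truth()
fluxes_abs = truth.to_absolute(q_uptake)

comp = BiomassComposition.from_yaml()
demand = anabolic_cofactor_demand(biomass_efflux(mu, comp), comp, mu)

ledger = gf.ledger_from_fluxes(fluxes_abs, model, demand)
gf.close_nadph(ledger)
gf.atp_accounting(ledger, gf.CofactorParams(po_ratio=1.5))
attr = gf.attribute_to_pathways(ledger, fluxes_abs, model)

print("rates in mmol gCDW^-1 h^-1")
for cof in ("NADH_UQH2", "NADPH", "ATP"):
    print(f"  {cof:>10}: production {ledger.production[cof]:6.2f}  "
          f"consumption {ledger.consumption[cof]:6.2f}")
print(f"\ntranshydrogenase flux {ledger.transhydrogenase_flux:.2f} "
      f"({100 * ledger.fraction_nadph_from_thd:.0f}% of NADPH production)")
print(f"oxidative phosphorylation ATP {ledger.oxphos_atp:.2f} "
      f"({100 * ledger.oxphos_atp / ledger.production['ATP']:.0f}% of ATP)")
print(f"ATP surplus (maintenance etc.) {ledger.atp_surplus:.2f}")
print("TCA share of NADH/UQH2 production: "
      f"{100 * attr['NADH_UQH2'].get('TCA', 0):.0f}%")
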