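# Synthetic default biomass composition and precursor/cofactor demand table.
#
# Mass fractions and precursor stoichiometries are editable defaults with
# magnitudes typical of aerobic heterotrophic bacteria (protein-dominated
# biomass, ~16 mmol NADPH and ~30-40 mmol ATP per gram of cells); they are
# NOT species measurements and every bundled analysis uses this same table.
mass_fractions:          # g per g total dry biomass (remainder = ash/other)
  protein: 0.55
  RNA: 0.14
  DNA: 0.03
  lipid: 0.10
  polysaccharide: 0.08
monomers_per_g:          # mmol monomer per g of component (polymerization basis)
  protein: 9.1           # ~110 g/mol average amino-acid residue
  RNA: 3.1
  DNA: 3.2
  lipid: 3.9             # acyl chains
  polysaccharide: 6.2
polymerization_atp:      # mol ATP per mol monomer polymerized
  protein: 4.3
  RNA: 2.4
  DNA: 3.4
  lipid: 1.0
  polysaccharide: 2.1
precursor_stoichiometry: # mmol precursor per g of component
  protein:  {OAA: 2.4, AKG: 1.6, PYR: 2.4, PEP: 0.65, PG3: 1.35, E4P: 0.33, R5P: 0.35, ACCOA: 0.3}
  RNA:      {R5P: 3.1, OAA: 1.0, PG3: 0.3}
  DNA:      {R5P: 3.2, OAA: 1.0}
  lipid:    {ACCOA: 28.0, DHAP: 0.6}
  polysaccharide: {G6P: 6.2}
cofactor_demand_per_precursor:  # mol per mol precursor drawn into biomass
  NADPH:     {OAA: 2.0, AKG: 2.5, PYR: 1.5, PEP: 1.0, PG3: 1.5, E4P: 2.0, R5P: 1.0, ACCOA: 2.1, G6P: 0.1, DHAP: 0.2}
  ATP:       {OAA: 0.5, AKG: 0.3, PYR: 0.4, PEP: 0.2, PG3: 0.5, E4P: 0.3, R5P: 1.2, ACCOA: 1.0}
  NADH_UQH2: {}
pathway_assignment:      # pathway of origin per precursor (carbon accounting)
  OAA: TCA
  AKG: TCA
  SUCCOA: TCA
  ACCOA: TCA
  PYR: TCA
  ASP: TCA
  PEP: EMP
  PG3: EMP
  GAP: EMP
  DHAP: EMP
  F6P: EMP
  G6P: EMP
  G1P: EMP
  R5P: PP
  E4P: PP
  S7P: PP
carbon_counts:
  OAA: 4
  AKG: 5
  SUCCOA: 4
  ACCOA: 2
  PYR: 3
  ASP: 4
  PEP: 3
  PG3: 3
  GAP: 3
  DHAP: 3
  F6P: 6
  G6P: 6
  G1P: 6
  R5P: 5
  E4P: 4
  S7P: 7
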