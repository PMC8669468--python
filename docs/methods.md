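# Methods

`gluconeoflux` quantifies carbon and energy fluxes for bacteria growing on
gluconeogenic substrates — carbon sources such as succinate that enter
metabolism at the TCA cycle and must be pushed "uphill" to sugar
phosphates. This note records the models, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Network models and atom transitions

A model is an ordered list of reactions with explicit carbon maps (one
letter per carbon), cofactor stoichiometry for three lumped pools
(NADH/UQH₂, NADPH, ATP) and a pathway tag. Metabolites that appear on both
sides of the reaction set are treated as balanced (intracellular,
steady-state); a header may override the set explicitly. The steady-state
constraint is S·v = 0 over balanced metabolites, with reversible reactions
carried as (net, exchange ≥ 0) pairs.

Two species files are bundled, for *Pseudomonas putida* KT2440 (63
reactions) and *Comamonas testosteroni* KF-1 (51 reactions) growing on
succinate. The reaction inventories are reconstructions from the declared
pathway topology — C4-dicarboxylate uptake, full TCA cycle, glyoxylate
shunt, anaplerosis/cataplerosis (PEP carboxykinase, PEP/pyruvate
carboxylases, malic enzyme, OAA decarboxylase), gluconeogenic EMP,
oxidative and non-oxidative PP pathway, ED pathway, transhydrogenases,
a CO₂ pool with unlabeled influx, carry-over influxes, and biomass
drains — at a granularity declared in each file header (e.g. PGM/ENO
split, GAPDH+PGK lumped). The *C. testosteroni* file omits G6P
dehydrogenase and 6PG dehydrogenase (no oxidative PP pathway), the
glycogen branch and the second transhydrogenase, and carries a single ED
route only where genome content supports it. Carbon maps follow standard
biochemistry: both CO₂ released in the first TCA turn derive from the OAA
carboxyls; isocitrate lyase splits isocitrate into succinate (C1, C2 +
acetyl carbons) and glyoxylate (OAA C3–C4). Rotationally symmetric
metabolites (succinate, fumarate) are scrambled by listing the two atom-map
orientations on each producing reaction, which share the flux equally.

Free-flux parameterization uses column-pivoted QR on S: the non-pivot
columns are the free reactions, and completion solves the pivot system.
The basis dimension is n_reactions − rank(S) and is checked in tests
against an independent symbolic rank computation.

## EMU simulation and its oracle

Labeling is simulated with the elementary-metabolite-unit decomposition:
starting from the measured fragments, atoms are traced backwards and the
minimal EMU set is kept, stratified by size. Each size solves one dense
linear system (models are small); condensation reactions enter as
convolutions of strictly smaller EMUs. The cascade is compiled once into
flat index arrays so that repeated evaluations inside the fitter cost only
the linear solves (~0.5 ms for the benchmark model).

Degenerate pools — zero total production under the current fluxes — are
excluded from the solve and assigned an unlabeled placeholder; if such a
pool actually feeds a live flux the simulation raises an error naming the
EMU. This keeps intermediate infeasible points encountered during
optimization well-defined (e.g. a glyoxylate shunt at exactly zero flux).

The independent oracle is a full 2^n isotopomer simulation: every pool is
the vector of its positional isotopomer fractions and the steady state is
found by fixed-point iteration of the flux-weighted mixing map, assuming
well-mixed, independent substrate pools. One numerical subtlety: the
"all pool sums equal 1" manifold is only neutrally stable under linear
transfer and becomes unstable when condensation cycles multiply pool sums,
so each sweep renormalizes every pool; the true solution is unaffected.
EMU and oracle agree to ≤ 1e−12 on the bundled toy networks (≤ 12 carbons)
across hundreds of seeded feasible flux draws, including reversible
exchange and scrambling.

Tracers are described positionally ([1,4-¹³C₄]-succinate = pattern `1001`)
with per-position purity (default 0.99). Simulated distributions are
natural-abundance-free; measured data are expected to be corrected first.
The correction is the inverse of the binomial ¹³C convolution (abundance
0.0107, carbon skeleton only), with small negatives clipped and the vector
renormalized — equivalent to the common correction tools for the
carbon-only case.

## Flux fitting

The estimator minimizes the variance-weighted SSR between simulated and
measured mass-isotopomer fractions over all tracers and replicates
jointly, plus rate measurements (secretion rates, biosynthetic effluxes).
Choices that matter:

- **Parameterization.** Equality constraints (S·v = 0, uptake fixed at
  100, disabled influxes at 0) are reduced to an affine null-space
  coordinate system. Exchange fluxes are optimized on the bounded
  transform x/(1+x) ∈ [0, 0.9999].
- **Sign constraints** on irreversible fluxes are smooth finite penalties
  (weight 10³), not exceptions, so every random start can recover.
- **Multi-start.** Starts are hit-and-run samples of the flux polytope
  interior (seeded); 100 starts by default. Each start runs a bounded
  trust-region least-squares solve with a modest evaluation budget; the
  winner is re-polished with tight tolerances. Ties break to the lowest
  start index. Identical seeds give bit-identical results.
- **Measurement SDs** are floored at 0.005 absolute (a common community
  convention; configurable). The biosynthetic-efflux imprecision option
  multiplies those rate SDs by exactly 2.
- **χ² acceptance.** A fit is accepted when SSR ≤ χ²₀.₉₅(dof) with dof =
  (number of fitted measurement entries) − (number of free parameters).
  Every MID entry is counted, as in common MFA software. The entries of
  one MID are not strictly independent (they sum to 1), but the generator's
  truncated-Gaussian-then-renormalize noise spreads variance so that the
  realized SSR at truth matches the all-entries count (measured ≈ 239 for
  258 entries on the benchmark); counting only n-per-fragment entries
  would reject about half of correctly specified fits.
- **Confidence intervals** are profile likelihood: the flux of interest is
  constrained (by eliminating one null-space coordinate), the remaining
  parameters re-optimized, and the 95% bound located where SSR crosses the
  optimum + 3.84, by doubling expansion and bisection to 1e−4 on the
  normalized flux scale. Unbounded directions stop at a box limit
  (3× uptake) and are flagged. The flux SD is (UB95 − LB95)/(2·1.96).
- **Unlabeled carry-over influxes** are gated on the corrected M+0 of the
  closest measured metabolite in a fully labeled tracer experiment:
  strictly greater than 0.01 enables the influx (bounded by the uptake);
  otherwise it is fixed to zero.

## Cofactor and ATP accounting

Production and consumption rates per lumped pool are the flux-weighted
sums of the reaction-level cofactor deltas (FADH₂/ubiquinol lumped with
NADH, as respiratory accounting usually does), in mmol gCDW⁻¹ h⁻¹; the
ledger refuses normalized fluxes. Anabolic demand comes from growth rate ×
biomass stoichiometry (below). The NADPH deficit is closed by a net
transhydrogenase conversion of NADH to NADPH, making the post-closure
NADPH balance exact by construction; oxidative phosphorylation then
converts respirable NADH/UQH₂ (production − transhydrogenase − reaction-
level consumption) to ATP at P/O = 1.5 (configurable, applied uniformly to
the lumped pool). The ATP surplus — total production minus anabolic plus
reaction-level consumption — absorbs maintenance and unmodeled processes.
Production attribution by pathway credits transhydrogenase-derived NADPH
and oxphos ATP to the pathways of the NADH they consumed. SDs propagate as
root-sum-of-squares of contributing flux SDs; flux–flux correlations are
ignored (a documented simplification). The adenylate energy charge is
(ATP + ½ADP)/(ATP + ADP + AMP).

## Biomass demand

Precursor effluxes are μ × Σ_components mass_fraction × stoichiometry, and
are assumed to depend on growth rate rather than on the carbon source.
The bundled composition/stoichiometry table is a synthetic default with
magnitudes typical of aerobic heterotrophs (protein-dominated biomass,
≈16 mmol NADPH and ≈30–40 mmol ATP per g cells, ATP polymerization costs
of ~4.3/2.4/3.4/2.1 per protein/RNA/DNA/polysaccharide monomer); it is not
a species measurement, and every bundled analysis uses the same table.
Pathway partitioning is carbon-weighted (rate × precursor carbon number)
over TCA/PP/EMP.

## Physiology

Growth rates come from log-linear regression of OD over a user-chosen
exponential window (the balanced-growth model); fits with R² < 0.95 are
flagged, as are OD↔dry-weight conversions with R² ≤ 0.750. Specific
exchange rates use the exponential-phase estimator q = μ·|dC/dX| from the
regression of concentration on biomass; biomass yield is the inverse
substrate slope. Carbon partitioning splits uptake carbon into biomass,
secretion and a residual ("other", i.e. CO₂ plus unaccounted).

## Proteomics statistics

For each protein in both conditions, the per-condition uncertainty is
√(sd²_across_replicates + mean²(within-replicate SE)) and the score is
Z = Δmean/(u₁ + u₂). The summed (not root-square-summed) denominator is
deliberate and conservative: under the null the statistic is narrower than
standard normal, so converting to two-sided normal p-values and controlling
with q-values (Storey, λ-grid π₀ smoothing; Benjamini–Hochberg available)
keeps the realized false-flag rate at or below the nominal 0.05. Proteins
with fewer than two finite replicates in a condition are demoted to
presence/absence calls. Note q-values control the false discovery rate,
not the family-wise error rate.

## Synthetic data and what the benchmarks show

The default scenario mirrors the study design: parallel labeling with
[1,4-¹³C₄]- and [2,3-¹³C₄]-succinate, three replicates each (six
isotopomer data sets), truncated-Gaussian MID noise of SD 0.005
renormalized to the simplex, rate noise of SD 1 (% of uptake) on the six
biosynthetic effluxes, optional unlabeled carry-over at ≤ 7% of uptake,
exponential growth (μ = 0.85 h⁻¹, 2 h lag, 2% multiplicative OD noise),
and a 1000-protein two-condition proteome with 10% true shifts of four
total-uncertainty units.

The benchmark network is a condensed 25-reaction model with the
*P. putida* succinate topology: TCA flux above the uptake rate,
scrambling at the symmetric C4 acids, an inactive glyoxylate shunt,
PEP-carboxykinase cataplerosis feeding ~21% of uptake into
gluconeogenesis, an inactive oxidative PP branch, a CO₂ outlet and six
biomass drains. Reactions are oriented irreversibly in the physiological
direction so that every free flux is structurally identifiable from the
two tracers — on a linear chain, exchange fluxes have no labeling
signature and would only add non-identifiable parameters. The full
63/51-reaction files are used for loading/validation/parameterization and
the gating example; the condensed model is the fitting benchmark.

Ground-truth fluxes for the benchmark satisfy S·v = 0 exactly; variants
(carry-over, active shunt) are built by constrained least-squares
projection of the edited truth back onto the flux cone. Noiseless data are
recovered to ≤ 1e−6 SSR and ~1e−9 relative flux error; with study-level
noise all free fluxes land within 2 SD of truth and the χ² test accepts.
CI calibration is measured on a two-free-flux dilution toy with plain
Gaussian noise (so the diagonal error model is exact): 90–99% coverage.

What passing these benchmarks does **not** show: robustness to real-data
pathologies — fragment-specific mass interferences, drifting natural
abundance correction residuals, metabolite channeling, non-stationary
labeling, model-topology error beyond the glyoxylate-shunt example — and
the bundled composition tables are placeholders, so absolute cofactor
numbers track the synthetic assumptions, not measured species values.

## Problem sizes and determinism

All stochastic procedures draw from `numpy` generators seeded per stage;
pipelines derive stage seeds from one master seed. Default sizes: 100
optimization starts per fit; 100 seeded flux draws per toy network for the
EMU/oracle equivalence; 100 replications for CI coverage; 1000 proteins.
The full test suite runs in a few minutes on one core.

## Known limitations

- Single net transhydrogenase closure; no PntAB/SthA directionality, no
  ferredoxin:NADP⁺ routes.
- Maintenance ATP is not modeled; it is read off the surplus.
- Natural-abundance correction covers the carbon skeleton only.
- The brute-force oracle is exponential in carbon count and intended for
  networks up to ~14 carbons.
- Profile CIs assume the χ²(1) threshold; near sign-constraint boundaries
  they are conservative (the coverage benchmark reflects this).
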