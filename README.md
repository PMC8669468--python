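# gluconeoflux

¹³C metabolic flux analysis and energy accounting for bacteria growing on
**gluconeogenic** substrates — carbon sources like succinate that enter
metabolism at the TCA cycle, so that sugar phosphates must be made by
running glycolysis backwards. The package is aimed at microbial
physiologists and metabolic engineers who want to quantify how such
organisms (e.g. *Pseudomonas putida*, *Comamonas testosteroni*) split a
high TCA flux between biosynthesis and energy generation, and how they
cover the anabolic NADPH bill when the oxidative pentose-phosphate pathway
is absent or silent.

## What it computes

- **Atom-mapped network models** (TSV dialect, 63-reaction *P. putida* and
  51-reaction *C. testosteroni* succinate reconstructions bundled), with
  validation, stoichiometric analysis and free-flux parameterization of
  S·v = 0.
- **EMU labeling simulation**: mass-isotopomer distributions (MIDs) of any
  fragment under positional ¹³C tracers, solved size-by-size through the
  elementary-metabolite-unit cascade, plus a brute-force 2ⁿ isotopomer
  oracle and binomial natural-abundance correction.
- **Flux estimation**: multi-start variance-weighted least squares against
  parallel-tracer MIDs and rate measurements,

  SSR = Σ ((sim − meas)/σ)², accepted when SSR ≤ χ²₀.₉₅(dof),

  with profile-likelihood 95% confidence intervals, flux SDs =
  (UB95 − LB95)/3.92, the CI-width precision score
  P = (w_unwashed/w_washed)², and gating of unlabeled carry-over influxes
  on corrected M+0 > 0.01.
- **Cofactor/ATP ledger**: production and consumption of NADH/UQH₂, NADPH
  and ATP from the fitted fluxes plus anabolic demand; the NADPH deficit
  is closed by transhydrogenase (NADH → NADPH), oxidative phosphorylation
  converts respirable NADH/UQH₂ at P/O = 1.5, and the ATP surplus absorbs
  maintenance. Adenylate energy charge EC = ([ATP] + ½[ADP]) / ([ATP] +
  [ADP] + [AMP]).
- **Physiology**: exponential growth rates, OD↔dry-weight conversion,
  specific uptake/secretion rates, yields, and carbon-fate partitioning.
- **Proteomics**: differential abundance via Z = Δmean/(u₁ + u₂) with
  two-component uncertainties, standard-normal p-values and Storey
  q-values.
- **Synthetic data** for every stage (tracer MIDs with noise and
  carry-over, growth curves, proteomes, adenylate pools), so the whole
  chain is testable without any downloads.

## Worked example

`examples/02_fit_fluxes.py` generates the default synthetic study — two
succinate tracers ([1,4-¹³C₄] and [2,3-¹³C₄]), three replicates each, MID
noise SD 0.005 — on the bundled succinate benchmark network and fits the
flux map (all fluxes in % of succinate uptake):

```
SSR 218.4 vs chi2 cutoff 289.0 (dof 251) -> accepted
  reaction   fitted     true
       SDH   126.16   126.00
       MDH    70.50    70.00
        CS    33.15    34.00
       ICD    33.02    34.00
       ICL     0.14     0.00
        ME    55.80    56.00
       PCK    20.63    21.00
       ENO    20.63    21.00

PCK 95% CI: 20.63 [17.28, 23.98] (SD 1.71) - the gluconeogenic flux out of the TCA cycle
```

The fit is statistically acceptable (SSR below the χ² cutoff), the TCA
fluxes above 100% of uptake and the inactive glyoxylate shunt are
recovered, and the profiled interval on PEP carboxykinase pins the
gluconeogenic flux at ~21% of uptake. The other examples cover labeling
simulation (`01`), the cofactor ledger with transhydrogenase closure
(`03`), growth physiology and energy charge (`04`) and the differential
proteome (`05`); each prints the numbers it computes and a line on what
they mean.

A thin CLI wraps the pipeline: `gflux model validate <path>`,
`gflux run --out DIR --seed 7`, `gflux compare runA runB --fluxes PCK`.

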