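# Methods

## The persistence model

The model asks whether sheer abundance can explain the persistence of a
costly, benefit-free extrachromosomal RNA element. Two subpopulations grow
exponentially: carriers *x*₁ with *N* element copies per cell, and
element-free cells *x*₂.

**Assumptions.**

* Copies impose a linear fitness cost: *r*₁ = *r*₂ − α*N* with
  α = *r*₂/*N**, i.e. *r*₁ = *r*₂(1 − *N*/*N**). The capacity *N** is the
  copy number at which carrier growth stops; the model is defined on the
  open range 0 ≤ *N* < *N**.
* Partitioning at division is purely random, so one designated daughter
  inherits zero of *N* copies with probability *µ* = (1/2)^*N*. Carrier
  births therefore split into carrier daughters at rate *r*₁(1−*µ*) and
  element-free daughters at rate *r*₁*µ* (the first column of the rate
  matrix sums to *r*₁ exactly — births are conserved).
* Element-free cells never regain the element: no horizontal transfer, no
  re-infection. The rate matrix is lower-triangular and its eigenvalues
  are the diagonal entries *r*₁(1−*µ*) and *r*₂.
* Growth is density-independent; *N* is a fixed per-cell parameter, not a
  fluctuating intracellular population.

One modelling alternative deserves note: (1/2)^*N* is the probability that
a *designated* daughter is empty; the probability that a division produces
*some* empty daughter is 2·(1/2)^*N* for *N* ≥ 1. The designated-daughter
form is implemented; the factor of two shifts nothing qualitative (it moves
the underflow threshold by one copy).

**Parameters.** `N` (copies per carrier cell, dimensionless count),
`Nstar` (capacity, same units; sets the per-copy burden α = r2/Nstar), `r2`
(element-free growth rate, default 1 so all times are in units of the
element-free exponential timescale). Defaults `N=10`, `Nstar=1000` are the
package's reference parameterisation; the qualitative behaviour is
insensitive to them.

**Closed form.** From **x**(0) = (1, 0), with eigenvalues
λ₁ = *r*₁(1−*µ*) < λ₂ = *r*₂ (strict for *N* ≥ 1), the solution is
*x*₁(t) = e^{λ₁t}, *x*₂(t) = c₂(e^{λ₂t} − e^{λ₁t}) with
c₂ = *r*₁*µ*/(λ₂ − λ₁), and the response time (first *x*₂ = *x*₁) is
*t** = log(1 + (λ₂−λ₁)/(*r*₁*µ*)) / (λ₂−λ₁). `analytic_state` is defined
only for this initial condition — its integration constants are specific
to it — while `simulate` accepts any non-negative start.

**The stability threshold is a floating-point statement.** `loss_probability`
evaluates (1/2)^*N* in 64-bit binary floating point with gradual underflow
(via exact power-of-two scaling, `ldexp`): the value is the smallest positive
subnormal 5.0 × 10⁻³²⁴ at *N* = 1074 and exactly 0.0 from *N* = 1075.
`stability_threshold()` finds that copy number by direct scan rather than
assuming it, and is documented as arithmetic-contract-dependent: on any
IEEE-754 double implementation it returns 1075. Past it the source term
vanishes identically and the carrier state is evolutionarily stable in the
simulation as well (x₂ stays exactly 0).

## Numerical choices

* **Integration**: `scipy.integrate.solve_ivp` with LSODA (adaptive,
  stiff-capable), rtol 1e-9, atol 1e-12, with the exact Jacobian supplied.
  The eigenvalue gap spans many orders of magnitude when *µ* is tiny, and
  x₂ starts at 0 and stays far below x₁ early on, so `atol` accepts a
  per-component pair; validation scales the x₂ tolerance by the amplitude
  c₂.
* **Response-time evaluation**: `log1p` for the small-ratio end; when
  *µ* is subnormal the ratio (λ₂−λ₁)/(*r*₁*µ*) can overflow even though
  *t** is finite, so the log is then computed as a difference of logs.
  When *r*₁*µ* itself underflows to 0, *t** is +∞ in scalar context and a
  `stable` sentinel (NaN `t_star`, `stable=True`) in sweep tables.
* **Crossing detection** (`crossing_time`): first sample with x₂ ≥ x₁
  (closed inequality), linearly interpolated between the bracketing
  samples. It is a purely numerical oracle for the closed form; the
  validation module holds their relative difference under 1e-4 over 100
  random parameter sets (observed: < 5e-7), and closed-form vs integrated
  states under 1e-6 on a log-spaced grid on [t*/100, 1.2 t*]. Draws are
  restricted to N ≤ 20 and r2·t* ≤ 600 so abundances at the crossing stay
  inside double range — a representability constraint of the oracle, not
  of the model.
* **Ranking ties**: competition ranking (tied features share the smallest
  applicable rank). Ties have probability zero for continuous estimated
  counts but the rule keeps the statistic deterministic, including on
  degenerate all-zero tables (flagged, not fatal).
* **Frequency threshold**: inclusive (≥ 0.05), matching the reporting
  behaviour of polymorphism-mode callers whose output the screen consumes;
  the threshold is a parameter and every run logs it.
* **Variant identity**: (replicon, position, alt allele), 1-based
  coordinates preserved end to end; the gene-context string is annotation
  payload only, so cosmetic annotation differences cannot split a variant
  into two rows. Duplicate reports of one variant in one sample keep the
  largest frequency.

## Open choices made here

* **Ranking metric**: `est_count` by default, with `tpm` available. The
  two orderings coincide only when effective lengths are equal, so the
  choice is exposed as a parameter and logged per run rather than asserted
  as canonical.
* **Confounding rule**: a variant is flagged for project *P* and label *L*
  when its presence pattern within *P* is exactly the set of *P*'s samples
  labelled *L*, that set is a proper subset of *P*'s samples, and it spans
  ≥ 2 growth conditions. Requiring exact equality (not mere overlap) keeps
  the flag conservative; the minimum-span rule prevents single-condition
  replicate structure from ever triggering it.
* **Sweep output**: the table keeps the six documented columns and adds an
  `error` column so invalid grid pairs are recorded in-band while the
  sweep continues.

## The synthetic generators

The real screens consume kallisto quantifications and breseq polymorphism
calls derived from 17 public RNA-seq runs of wildtype SK36 monocultures
(four projects, several growth conditions, labelled replicates; the layout
ships as `SK36_RNASEQ_SAMPLES`). The generators emulate those downstream
products, not the reads:

* `synth_abundance` draws mRNA counts i.i.d. log-normal (log-scale mean
  5.0, sigma 2.0 — a several-orders-of-magnitude spread typical of
  bacterial transcriptomes) for 2270 genes, places the focal transcript's
  count strictly between the order statistics flanking its target rank,
  and adds rRNA decoys far above every mRNA (as in undepleted total-RNA
  libraries) plus sRNA decoys, so class exclusion demonstrably matters.
  The rank statistic is expressly non-parametric, so the log-normal is a
  testing device, not a distributional claim. Effective length is
  length − 100 floored at 1 — a fragment-length surrogate adequate for TPM
  arithmetic.
* `synth_variants` plants chosen variants into exactly the samples carrying
  chosen replicate labels (frequencies uniform in a per-variant band, e.g.
  8–11%) and scatters background variants Poisson-per-sample at globally
  unique positions, so background can never recur across samples.
  `default_polymorphism_scenario` reproduces the study-shaped case: one
  synonymous change present in 2 of 3 replicates of a single-condition
  project, and two mutations riding replicate label "2" across four
  conditions of another project — the pair the confounding screen must
  flag, and does, uniquely, across 100 seeded runs.

What passing these tests shows is that the statistics recover planted
truth under clean, independent noise. What they cannot show: robustness to
correlated quantification error, mapping artefacts, partial annotation, or
frequency estimation noise near the 5% threshold in real read data — all
upstream of this package's inputs.

## Known limitations

* The model is deterministic; it has no stochastic fluctuation of
  intracellular copy number, which is the obvious candidate mechanism for
  the spontaneous element loss observed experimentally in cultures. No
  density dependence, no horizontal transfer, no parameter fitting.
* The stability threshold is exactly the double-precision underflow
  exponent; in extended or arbitrary precision the threshold moves. That
  dependence is the point of the statistic, not an accident, and it is
  surfaced in the API documentation.
* `analytic_state` covers only the (1, 0) initial condition; other starts
  go through the ODE solver.
* The acceptance script's 100-draw validation and the 2270-gene tables run
  in seconds; problem sizes are stated in the script and tests and were
  chosen to exercise full study scale (2270 genes, 17 samples) where that
  scale is the claim.
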