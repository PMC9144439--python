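# Methods

## The prediction model

`structgp` fits the single-random-effect mixed model

    y = Xβ + Zu + ε,    u ~ N(0, I σu²),    ε ~ N(0, I σe²)

where `y` (length N) holds the training phenotypes, `X` is the
fixed-effect design and `Z` the N × M encoded genotype matrix. Marker
effects `u` share one variance (the RR-BLUP assumption), so the model is
equivalent to kernel ridge regression with the genomic kernel K = ZZᵀ
(GBLUP). Only an intercept is fitted by default: the panels this package
targets are single-location evaluations without further design factors, and
the fixed-effect design is exposed for users who have them.

### REML estimation

Variance components are profiled down to the ratio λ = σe²/σu². The model
is rotated into the orthogonal complement of col(X) via a full QR of X;
with ξᵢ the eigenvalues of the restricted kernel Q₂ᵀKQ₂ and ηᵢ the rotated
responses, the restricted log-likelihood is

    ℓ(λ) = ½[(N−q)(ln((N−q)/2π) − 1 − ln Σ ηᵢ²/(ξᵢ+λ)) − Σ ln(ξᵢ+λ)]

evaluated in O(N) per λ after one O(N³) decomposition. λ is maximised by a
101-point grid on log λ ∈ [−10, 10] followed by bounded Brent refinement
(tolerance 1e-8 on log λ). A maximiser at the bracket edge is clamped and
flagged `boundary=True` (effectively σu² → 0 or σe² → 0) rather than
raised; an all-zero `Z` or a constant `y` short-circuits to the ordinary
least-squares boundary fit. At the optimum, σu² = Σ ηᵢ²/(ξᵢ+λ) / (N−q),
β is the GLS estimate, and `u = Zᵀ(K+λI)⁻¹(y−Xβ)`.

REML was chosen over ML for the usual reason — variance components
unbiased by the fixed-effect estimation — and because it is what the
standard mixed-model software this workflow replaces computes. Residuals
carry their own variance σe², distinct from σu²; the two-variance form is
the only one under which the model is identified.

### Prediction

GEBVs are `Z_test u` on the centred scale; test genotypes must be encoded
with the *training* column means (the `GenotypeEncoder` carries them).
Predictive ability is invariant to the intercept, so phenotype-scale output
(`include_fixed=True`) is optional. The marker-effect and kernel
formulations agree to numerical precision; the test suite asserts this at
1e-8 relative tolerance and checks the REML optimum against a 401-point
brute-force likelihood grid.

## Genotype handling

- **Coding.** Inbred material: homozygote classes coded {0, 1}; missing is
  NaN. Heterozygous VCF calls are treated as missing by default (residual
  heterozygosity in a selfing crop is usually artefactual), or coded
  {0, 1, 2} dosages with `het_policy="dosage"` — the solver accepts either.
- **Filters.** A marker is kept iff MAF > 0.05 and missing fraction < 0.50,
  both strict, evaluated jointly on the input (VCFtools-style simultaneous
  flags); MAF uses non-missing calls only.
- **Subsampling.** Per-chromosome quotas by largest-remainder apportionment
  (quotas sum exactly to the target; each quota is the floor or ceiling of
  its proportional share), then uniform draws without replacement within
  chromosomes. Quotas are deterministic; only the within-chromosome draw
  uses the seed.
- **Imputation.** Marker-mean imputation, then centring by the same mean,
  so imputed cells are exactly 0 — the simplest defensible choice and
  swappable behind `GenotypeEncoder`.

## The synthetic cohort generator

The generator exists so the full analysis is testable without any data
download. It emulates a structured germplasm panel statistically:

- **Composition** (defaults): 628 accessions — 223/261 Andean/Mesoamerican
  landraces, 60/84 breeding lines — and 11 chromosomes as contiguous
  near-equal marker blocks.
- **Divergence**: ancestral frequencies uniform on [0.05, 0.95]; pool
  frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F). The default
  F = 0.4 reflects the strong differentiation between the two bean gene
  pools; the Hudson estimator on simulated landraces recovers the knob to
  within sampling error (tested at ±0.05).
- **Inbreeding**: each genotype is one Bernoulli draw from its pool
  frequency — fully inbred {0,1} lines, matching the solver's default
  coding.
- **Breeding lines**: each pool has a notional founder set of
  `n_founders = 20`; breeding lines draw from the allele frequencies
  realized in a `round(founder_fraction × 20)`-founder subset
  (default fraction 0.5). The subset's drift makes breeding lines of a pool
  mutually closer than they are to that pool's landraces — the qualitative
  "diversity narrowed through breeding" structure — with the fraction as
  the single knob.
- **Traits**: `n_qtl` markers get i.i.d. standard normal effects on the
  mean-imputed centred genotypes; noise is scaled against the *realized*
  genetic variance so var(g)/var(y) ≈ h² (exactly pure-genetic at h²=1,
  pure-noise at h²=0). QTLs are resampled from markers with at least one
  observed call, so an all-missing column can never carry an effect.
- **Missingness**: completely at random at `missing_rate` (default 0).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and shared haplotypes
(markers are independent given pool frequencies), pedigree relatedness
beyond the founder-drift approximation, genotype-by-environment variation,
dominance/epistasis, non-random missingness, and ascertainment bias in
marker discovery. Two consequences worth naming:

1. At fst = 0 the *landrace* strata are exactly exchangeable between pools
   (any two-pool statistic sits in its permutation null band — tested).
   The full cohort is not: breeding lines carry pool-specific founder
   drift by construction, so the pool labelling separates weakly even
   without divergence.
2. Marker-independence caps how much training-set composition can matter.
   Adding the same-pool breeding half to the landrace training set helps
   (G2 > G1, G5 > G4 in expectation, via the founder drift shared between
   the A1/A2 halves), but by-pool versus random selection of that half
   (G7 vs G8) is a statistical tie here: a random half-split gives each
   test line the same expected number of same-pool relatives in training
   as the stratified split, leaving only a second-order stability effect
   (measured at −0.008 ± 0.010 over 100 simulated cohorts). On real panels,
   family structure and LD can break this tie; the simulation cannot.

## Experiment designs

- **CV grid**: per cell (population fraction × SNP count) and replicate,
  the landrace set is subsampled to the fraction, markers subsampled
  proportionally, and 10-fold CV run within the subsample; one Pearson r
  per replicate is computed on the pooled held-out predictions of all ten
  folds (not per-fold averages), then averaged over replicates. "Population
  size" thus means the effective training+testing pool, and every random
  choice is seeded per (cell, replicate). Defaults: fractions
  10–100% in seven steps, SNP counts 100–7000 plus "all", 100 replicates.
- **Optimum rule**: (opt_pop, opt_snp) is the smallest-fraction, then
  smallest-SNP-count cell whose mean r is within `tolerance` (default 0.01
  absolute) of the grid maximum — an explicit plateau rule in place of an
  informal "no further significant improvement" judgement.
- **Gene-pool designs**: five deterministic fits per trait — combined
  landraces predicting all/Andean/Mesoamerican breeding lines, and each
  pool's landraces predicting its own breeding lines — with top-30 and
  top-30% overlap ratios.
- **Scenarios G1–G8**: per-pool random half-splits of the breeding lines
  (sizes ⌊n/2⌋/⌈n/2⌉; 30/30 and 42/42 at the default composition) plus a
  pooled random 72/72 split drawn from the same seed stream so the by-pool
  versus random comparison (G7 vs G8) is paired. Training and testing sets
  are asserted disjoint in every design; fits are deterministic given the
  plan, and replication across plans is exposed via `--plan-reps`.

## Numerical and scale choices

- PCA: SVD of the centred (not variance-scaled) matrix — the
  population-genetics default, keeping PC geometry tied to allele-frequency
  divergence; component signs fixed by forcing each component's
  largest-magnitude loading positive.
- Top-k ties: stable sort by input (accession) order; fraction→k rounds
  half away from zero with a floor of 1; the "top" direction defaults to
  descending with a per-trait override (for smaller-is-better traits).
- Test problem sizes: the suite runs cohorts of a few hundred to 628
  accessions at 300–2000 markers, with 5–200 replicates per property —
  sizes at which every Monte-Carlo tolerance used (±0.05 on recovered h²
  and Fst, 3 SE bands on overlap means) was chosen from the statistic's
  sampling error, not fitted to outcomes.

## Known limitations

- REML profiles a single kernel; multi-kernel, G×E and Bayesian
  marker-effect models are out of scope.
- The λ bracket [e⁻¹⁰, e¹⁰] clamps extreme heritabilities to boundary fits
  rather than extrapolating.
- `find_optimum` needs a complete grid for the trait and does not
  interpolate between cells.
- The generator's independence assumptions above; in particular, scenario
  contrasts that depend on family structure (G7 vs G8) are near-null in
  simulation and should be read as arithmetic/plumbing checks, not as
  reproducing field results.
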