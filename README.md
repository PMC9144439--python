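# structgp

Genomic prediction with training-set optimization under population
structure, for crop germplasm panels that split into strongly diverged
gene pools — modelled on the common bean (*Phaseolus vulgaris*), whose
collections combine Andean and Mesoamerican landraces with
diversity-narrowed breeding lines.

The package is for breeders and quantitative geneticists who want to ask,
on such a panel: how large a training population and how many SNPs does a
prediction model need, does combining or assigning gene pools in the
training set matter, and does adding breeding lines — selected by gene pool
or at random — to a landrace training set improve prediction of the
remaining breeding lines?

## The model

The core is ridge-regression BLUP (RR-BLUP), the single-random-effect mixed
model

```
y = Xβ + Zu + ε,   u ~ N(0, I σu²),   ε ~ N(0, I σe²)
```

with `y` the training phenotypes, `X` an intercept column, and `Z` the
N × M genotype matrix (inbred homozygotes coded {0, 1}, mean-imputed and
column-centred). Variance components are estimated by REML: the restricted
likelihood is profiled down to the single ratio λ = σe²/σu² using the
spectral decomposition of the genomic kernel ZZᵀ, so each evaluation is
O(N) after one O(N³) decomposition, and λ is found by a coarse grid plus
Brent refinement. Marker effects are the ridge solution
`u = Zᵀ(ZZᵀ + λI)⁻¹(y − Xβ)` and genomic estimated breeding values for
candidates are `GEBV = Z_test u` — algebraically identical to the kernel
(GBLUP) formulation, which the test suite uses as an oracle.

Around the solver, the package provides:

- **`simulate`** — synthetic cohorts with the panel's structure: two
  Balding–Nichols gene pools at a configurable Fst, landrace and
  (founder-narrowed) breeding strata, additive traits at a requested
  heritability. Defaults reproduce the reference composition: 628
  accessions = 484 landraces (223 Andean + 261 Mesoamerican) + 144 breeding
  lines (60 + 84) on 11 chromosomes.
- **`genotypes`** — VCF input (via cyvcf2), MAF/missingness filters
  (strictly >5% MAF, <50% missing), largest-remainder proportional marker
  subsampling per chromosome, and training-scale encoding.
- **`structure`** — centred-genotype PCA with a deterministic sign
  convention and a silhouette pool-separation score.
- **`evaluation`** — predictive ability (Pearson r of GEBV vs observed in
  the testing set) and top-k / top-fraction overlap ratios.
- **`experiments`** — the three analyses: the population-size × SNP-number
  cross-validation grid with the (opt_pop, opt_snp) plateau rule; the five
  gene-pool combine/assign designs (An+M→An+M, An+M→An, An+M→M, An→An,
  M→M); and the G1–G8 training-set scenarios built from random half-splits
  of the breeding lines (A1/A2, M1/M2, or a pooled random 72/72 split).

## Worked example

Fit on the 484 simulated landraces, predict the 144 breeding lines
(`examples/03_fit_and_predict.py`):

```python
from structgp import (SimConfig, simulate_cohort, simulate_phenotypes,
                      GenotypeEncoder, fit_mixed_model, predict_gebv,
                      predictive_ability, topk_overlap)

G, meta = simulate_cohort(SimConfig(n_markers=2000, seed=5))
y, _ = simulate_phenotypes(G, h2=0.6, n_qtl=100, seed=6)
is_landrace = (meta["class"] == "landrace").to_numpy()
train = G.take_accessions(meta.loc[is_landrace, "accession_id"])
test = G.take_accessions(meta.loc[~is_landrace, "accession_id"])
enc = GenotypeEncoder().fit(train)
fit = fit_mixed_model(y[is_landrace], enc.transform(train))
gebv = predict_gebv(fit, enc.transform(test))
```

This prints:

```
variance components: var_u=0.02069, var_e=11.16, lambda=539, REML loglik=-1348.69
predictive ability (r) on 144 breeding lines: 0.453
top-30 overlap ratio: 0.400
top-30% overlap ratio: 0.512
```

The predictive ability of 0.45 on an h² = 0.6 trait sits, as it should,
below the √h² ≈ 0.77 ceiling (finite training set, markers in imperfect
linkage with the 100 QTLs); the top-30 ratio says 12 of the 30
best-predicted breeding lines are truly among the 30 best. The other
examples cover simulation and I/O (`01`, `02`), structure (`04`), the CV
grid and its optimum (`05`), and the gene-pool and G1–G8 scenario designs
(`06`).

A thin CLI mirrors the library: `structgp simulate | filter | fit | pca |
cv | pools | scenarios` (see `structgp --help`).

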