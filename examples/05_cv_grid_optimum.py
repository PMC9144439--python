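"""Training-size x marker-number cross-validation grid and its optimum.

For each (population fraction, SNP count) cell the landrace set is
subsampled, markers drawn proportionally per chromosome, and replicated
10-fold cross-validation run; the optimum is the cheapest cell whose mean
predictive ability sits within a tolerance of the grid maximum.
"""

from structgp import (
    CVDesign,
    SimConfig,
    find_optimum,
    run_cv_grid,
    simulate_cohort,
    simulate_phenotypes,
    summarize_cv_grid,
)

G, meta = simulate_cohort(SimConfig(n_markers=1500, h2=0.8, seed=8))
y, _ = simulate_phenotypes(G, h2=0.8, n_qtl=100, seed=9)
landraces = meta.loc[meta["class"] == "landrace", "accession_id"].tolist()

# a desk-scale grid; the full design uses 7 fractions x 11 SNP counts x 100 reps
design = CVDesign(
    folds=10, reps=3,
    population_fractions=(0.2, 0.5, 1.0),
    snp_counts=(100, 500, "all"),
    seed=10,
)
grid = summarize_cv_grid(run_cv_grid(G, y, landraces, design))
print(grid.pivot(index="fraction", columns="snp_count", values="mean_r").round(3))

opt = find_optimum(grid, "trait", tolerance=0.01, n_markers_all=G.n_markers)
print(f"optimum: opt_pop={opt.opt_pop:.0%} of landraces, opt_snp={opt.opt_snp}, "
      f"mean r={opt.mean_r:.3f}")
# Mean r rises with training size and marker count, then plateaus; the
# optimum reports where adding more of either stops paying.
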