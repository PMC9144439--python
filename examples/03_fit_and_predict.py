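"""Fit RR-BLUP on the landraces and predict the breeding lines.

The REML mixed model y = Xb + Zu + e estimates the marker-effect and
residual variances, then GEBV = Z_test u scores every breeding line.
Predictive ability is the Pearson r between GEBVs and the (here simulated,
hence known) phenotypes of the testing set; the top-30 overlap ratio is the
fraction of the 30 best-predicted lines that are truly among the 30 best.
"""

import numpy as np

from structgp import (
    GenotypeEncoder,
    SimConfig,
    fit_mixed_model,
    predict_gebv,
    predictive_ability,
    simulate_cohort,
    simulate_phenotypes,
    topk_overlap,
)

G, meta = simulate_cohort(SimConfig(n_markers=2000, seed=5))
y, _ = simulate_phenotypes(G, h2=0.6, n_qtl=100, seed=6)

is_landrace = (meta["class"] == "landrace").to_numpy()
train = G.take_accessions(meta.loc[is_landrace, "accession_id"])
test = G.take_accessions(meta.loc[~is_landrace, "accession_id"])

enc = GenotypeEncoder().fit(train)
fit = fit_mixed_model(y[is_landrace], enc.transform(train))
gebv = predict_gebv(fit, enc.transform(test))

print(f"variance components: var_u={fit.var_u:.4g}, var_e={fit.var_e:.4g}, "
      f"lambda={fit.lambda_:.3g}, REML loglik={fit.reml_loglik:.2f}")
print(f"predictive ability (r) on {test.n_accessions} breeding lines: "
      f"{predictive_ability(gebv, y[~is_landrace]):.3f}")
print(f"top-30 overlap ratio: {topk_overlap(gebv, y[~is_landrace], k=30):.3f}")
print(f"top-30% overlap ratio: {topk_overlap(gebv, y[~is_landrace], fraction=0.3):.3f}")
# r around sqrt(h2) is the ceiling for a perfectly estimated model; values
# well below it reflect finite training size and marker density.
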