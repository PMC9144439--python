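"""Marker filtering and proportional subsampling on a cohort with missing calls.

Markers are kept when MAF > 5% and missingness < 50% (strict inequalities),
then subsampled to a target count apportioned across chromosomes by
largest-remainder shares of their marker counts.
"""

from structgp import (
    SimConfig,
    filter_markers,
    impute_and_encode,
    simulate_cohort,
    subsample_markers,
)

G, meta = simulate_cohort(SimConfig(n_markers=3000, missing_rate=0.15, seed=3))
filtered, report = filter_markers(G, maf_min=0.05, max_missing=0.50)
print("filter report:", report.to_dict())

sub = subsample_markers(filtered, target_n=1000, seed=4)
print("per-chromosome counts after subsampling:")
print(sub.marker_map["chrom"].value_counts().sort_index().to_string())

Z, encoder = impute_and_encode(sub)
print(f"encoded matrix: {Z.shape}, column means ~0 "
      f"(max |mean| = {abs(Z.mean(axis=0)).max():.2e}), no missing values")
# The encoder keeps the training column means so that test-set accessions
# can later be encoded on the same scale.
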