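"""Gene-pool designs and the G1-G8 training-set optimization scenarios.

First the combine/assign designs (landraces predicting breeding lines with
pools merged or matched), then the two-step scenarios: G1-G3 test Andean
breeding lines while adding none / the Andean half / both pool halves to
the training set; G4-G6 mirror this for the Mesoamerican pool; G7 and G8
compare adding half the breeding lines selected by pool versus at random.
"""

from structgp import (
    SimConfig,
    make_split_plan,
    run_pool_prediction,
    run_scenarios,
    simulate_cohort,
    simulate_phenotypes,
)

G, meta = simulate_cohort(
    SimConfig(n_markers=1000, founder_fraction=0.3, h2=0.6, seed=11)
)
y, _ = simulate_phenotypes(G, h2=0.6, n_qtl=100, seed=12)

pools = run_pool_prediction(G, y, meta)
print("gene-pool designs (train -> test):")
print(pools[["design", "r", "n_train", "n_test", "top_k_ratio"]].round(3).to_string(index=False))

plan = make_split_plan(meta, seed=13)
print(f"\nsplit plan: |A1|={len(plan.a1)}, |A2|={len(plan.a2)}, "
      f"|M1|={len(plan.m1)}, |M2|={len(plan.m2)}")
scen = run_scenarios(G, y, meta, plan)
print(scen[["group", "r", "n_train", "n_test"]].round(3).to_string(index=False))
# Adding the same-pool breeding half (G2 vs G1, G5 vs G4) typically raises r
# because breeding lines are mutually closer than they are to landraces.
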