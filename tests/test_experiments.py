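"""Split plans, CV grid mechanics, optimum rule, pool and scenario designs."""

import numpy as np
import pandas as pd
import pytest

from structgp import (
    CVDesign,
    SimConfig,
    find_optimum,
    make_split_plan,
    run_cv_grid,
    run_pool_prediction,
    run_scenarios,
    scenario_groups,
    simulate_cohort,
    simulate_phenotypes,
    summarize_cv_grid,
)
from structgp.experiments import _fit_design, _make_folds


def toy_metadata(n_a_land=6, n_m_land=6, n_a_breed=5, n_m_breed=4):
    rows = []
    for n, pool, cls, pre in [
        (n_a_land, "Andean", "landrace", "AL"),
        (n_m_land, "Mesoamerican", "landrace", "ML"),
        (n_a_breed, "Andean", "breeding", "AB"),
        (n_m_breed, "Mesoamerican", "breeding", "MB"),
    ]:
        rows += [(f"{pre}{i}", pool, cls) for i in range(n)]
    return pd.DataFrame(rows, columns=["accession_id", "pool", "class"])


class TestSplitPlan:
    def test_reference_panel_half_split_sizes(self, small_cohort):
        """60 Andean -> 30/30, 84 Mesoamerican -> 42/42, combined halves 72."""
        _, meta = small_cohort
        plan = make_split_plan(meta, seed=0)
        assert len(plan.a1) == len(plan.a2) == 30
        assert len(plan.m1) == len(plan.m2) == 42
        assert len(set(plan.a1 + plan.m1)) == 72
        assert len(plan.rand_add) == len(plan.rand_test) == 72

    def test_odd_pool_partitions(self):
        meta = toy_metadata(n_a_breed=5)
        plan = make_split_plan(meta, seed=1)
        assert sorted(len(x) for x in (plan.a1, plan.a2)) == [2, 3]
        ab = set(meta.loc[(meta["pool"] == "Andean") & (meta["class"] == "breeding"),
                          "accession_id"])
        assert set(plan.a1) | set(plan.a2) == ab
        assert not set(plan.a1) & set(plan.a2)

    def test_seeded_reproducibility(self, small_cohort):
        _, meta = small_cohort
        p1, p2 = make_split_plan(meta, seed=9), make_split_plan(meta, seed=9)
        assert (p1.a1, p1.m1, p1.rand_add) == (p2.a1, p2.m1, p2.rand_add)
        p3 = make_split_plan(meta, seed=10)
        assert p1.a1 != p3.a1

    def test_no_breeding_lines_raises(self):
        meta = toy_metadata(n_a_breed=0, n_m_breed=0)
        with pytest.raises(ValueError):
            make_split_plan(meta, seed=0)


class TestScenarioGroups:
    def test_compositions(self, small_cohort):
        _, meta = small_cohort
        plan = make_split_plan(meta, seed=2)
        groups = scenario_groups(meta, plan)
        assert set(groups) == {f"G{i}" for i in range(1, 9)}
        landraces = set(meta.loc[meta["class"] == "landrace", "accession_id"])
        train1, test1 = groups["G1"]
        assert set(train1) == landraces  # G1 trains on landraces only
        # G3/G6/G7 additional set is A1 + M1 = 72 lines
        for g in ("G3", "G6", "G7"):
            train, _ = groups[g]
            assert len(set(train) - landraces) == 72
        assert set(groups["G7"][1]) == set(plan.a2) | set(plan.m2)
        for train, test in groups.values():
            assert not set(train) & set(test)
            assert len(test) > 0

    def test_overlap_aborts(self, small_cohort, small_trait):
        G, _ = small_cohort
        y, _ = small_trait
        ids = G.accession_ids
        with pytest.raises(ValueError, match="overlap"):
            _fit_design(G, pd.Series(y), ids[:50], ids[40:60])

    def test_scenario_table_shape(self, small_cohort, small_trait):
        G, meta = small_cohort
        y, _ = small_trait
        plan = make_split_plan(meta, seed=3)
        out = run_scenarios(G, {"t1": y}, meta, plan)
        assert list(out["group"]) == [f"G{i}" for i in range(1, 9)]
        assert out["r"].between(-1, 1).all()
        assert (out.loc[out["group"] == "G7", "n_test"] == 72).all()


class TestCvGrid:
    def test_default_design_is_seven_by_eleven(self):
        d = CVDesign()
        assert len(d.population_fractions) == 7
        assert len(d.snp_counts) == 11
        assert d.folds == 10 and d.reps == 100

    def test_fold_partition(self, rng):
        ids = [f"x{i}" for i in range(23)]
        folds = _make_folds(ids, 5, rng)
        flat = [a for f in folds for a in f]
        assert sorted(flat) == sorted(ids)  # each id in exactly one fold
        assert {len(f) for f in folds} <= {4, 5}

    def test_grid_shape_and_reproducibility(self):
        cfg = SimConfig(
            n_landrace_andean=30, n_landrace_meso=30,
            n_breeding_andean=2, n_breeding_meso=2,
            n_markers=120, h2=0.8, n_qtl=30, seed=40,
        )
        G, meta = simulate_cohort(cfg)
        y, _ = simulate_phenotypes(G, h2=0.8, n_qtl=30, seed=41)
        land = meta.loc[meta["class"] == "landrace", "accession_id"].tolist()
        design = CVDesign(
            folds=4, reps=2, population_fractions=(0.5, 1.0),
            snp_counts=(50, "all"), seed=42,
        )
        grid = run_cv_grid(G, y, land, design)
        assert len(grid) == 2 * 2 * 2  # cells x reps
        assert set(zip(grid["fraction"], grid["snp_count"])) == {
            (0.5, 50), (0.5, "all"), (1.0, 50), (1.0, "all")
        }
        grid2 = run_cv_grid(G, y, land, design)
        pd.testing.assert_frame_equal(grid, grid2)  # bit-reproducible

        summary = summarize_cv_grid(grid)
        assert len(summary) == 4
        reps_per_cell = grid.groupby(["fraction", "snp_count"])["rep"].count()
        assert (reps_per_cell == design.reps).all()

    def test_snp_count_beyond_available_raises(self, small_cohort, small_trait):
        G, meta = small_cohort
        y, _ = small_trait
        land = meta.loc[meta["class"] == "landrace", "accession_id"].tolist()
        design = CVDesign(folds=5, reps=1, population_fractions=(1.0,),
                          snp_counts=(G.n_markers + 1,))
        with pytest.raises(ValueError, match="exceeds"):
            run_cv_grid(G, y, land, design)


class TestFindOptimum:
    def grid(self, rows):
        return pd.DataFrame(rows, columns=["trait", "fraction", "snp_count", "mean_r"])

    def test_flat_grid_picks_cheapest(self):
        rows = [("t", f, s, 0.5) for f in (0.1, 0.5, 1.0) for s in (100, 500)]
        opt = find_optimum(self.grid(rows), "t")
        assert (opt.opt_pop, opt.opt_snp) == (0.1, 100)

    def test_strictly_increasing_grid_with_zero_tolerance(self):
        rows = [("t", f, s, f + s / 1000) for f in (0.1, 0.5, 1.0) for s in (100, 500)]
        opt = find_optimum(self.grid(rows), "t", tolerance=0.0)
        assert (opt.opt_pop, opt.opt_snp) == (1.0, 500)

    def test_plateau_rule(self):
        """A plateau starting at (40%, 2000) is found at its cheapest corner."""
        fracs = (0.1, 0.2, 0.4, 1.0)
        snps = (500, 1000, 2000, 5000)
        rows = []
        for f in fracs:
            for s in snps:
                r = 0.8 if (f >= 0.4 and s >= 2000) else 0.5
                rows.append(("t", f, s, r))
        opt = find_optimum(self.grid(rows), "t", tolerance=0.01)
        assert (opt.opt_pop, opt.opt_snp) == (0.4, 2000)
        assert opt.mean_r == pytest.approx(0.8)

    def test_all_sentinel_resolution(self):
        rows = [("t", 1.0, "all", 0.9), ("t", 1.0, 100, 0.9)]
        opt = find_optimum(self.grid(rows), "t", n_markers_all=400)
        assert opt.opt_snp == 100  # 100 < 400, cheaper on the plateau

    def test_unknown_trait_raises(self):
        with pytest.raises(ValueError):
            find_optimum(self.grid([("t", 1.0, 100, 0.5)]), "other")


class TestPoolPrediction:
    def test_five_designs_reported(self, small_cohort, small_trait):
        G, meta = small_cohort
        y, _ = small_trait
        out = run_pool_prediction(G, y, meta)
        assert list(out["design"]) == [
            "An+M->An+M", "An+M->An", "An+M->M", "An->An", "M->M"
        ]
        assert (out["n_train"] == [484, 484, 484, 223, 261]).all()
        assert (out["n_test"] == [144, 60, 84, 60, 84]).all()
        assert out["top_k_ratio"].between(0, 1).all()
        assert out["top_frac_ratio"].between(0, 1).all()

    def test_null_trait_has_null_predictive_ability(self, small_cohort):
        """With h2 = 0 every design's r stays inside the null band 3/sqrt(n)."""
        G, meta = small_cohort
        y, _ = simulate_phenotypes(G, h2=0.0, n_qtl=40, seed=77)
        out = run_pool_prediction(G, y, meta, compute_overlap=False)
        bound = 3.0 / np.sqrt(out["n_test"].to_numpy())
        assert (out["r"].abs().to_numpy() <= bound).all()

    def test_heritable_trait_beats_null_band(self):
        """Shared-QTL h2=0.8 trait: An->An exceeds the h2=0 null band (20-seed mean)."""
        rs = []
        for seed in range(20):
            cfg = SimConfig(n_markers=300, h2=0.8, n_qtl=50, seed=200 + seed)
            G, meta = simulate_cohort(cfg)
            y, _ = simulate_phenotypes(G, h2=0.8, n_qtl=50, seed=900 + seed)
            out = run_pool_prediction(G, y, meta, compute_overlap=False)
            rs.append(out.loc[out["design"] == "An->An", "r"].iloc[0])
        assert np.mean(rs) > 3.0 / np.sqrt(60)
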