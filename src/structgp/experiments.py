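"""Prediction designs: CV grids, gene-pool designs, training-set scenarios.

Three analyses over a genotyped, phenotyped, two-gene-pool cohort:

1. **Cross-validation grid** (`run_cv_grid`): predictive ability of the
   landrace set across a population-size x marker-number grid (defaults:
   10/20/40/50/60/80/100% of the landraces x 100...7000/all SNPs), each cell
   a mean over replicated 10-fold cross-validations; `find_optimum` then
   picks the cheapest cell on the plateau of the grid maximum (opt_pop,
   opt_snp).
2. **Gene-pool combine/assign designs** (`run_pool_prediction`): landraces
   predicting breeding lines with the pools combined or assigned —
   An+M->An+M, An+M->An, An+M->M, An->An, M->M — with optional top-k
   overlap ratios.
3. **Training-set optimization scenarios** (`run_scenarios`): groups G1-G8
   built from half-splits of the breeding lines (A1/A2 Andean, M1/M2
   Mesoamerican, or a pooled random split), testing whether adding half the
   breeding lines — selected by gene pool versus at random — to a landrace
   training set improves prediction of the remaining breeding lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import predictive_ability, topk_overlap
from .genotypes import GenotypeMatrix, GenotypeEncoder, subsample_markers
from .model import fit_mixed_model, predict_gebv

__all__ = [
    "CVDesign",
    "SplitPlan",
    "OptimumConfig",
    "make_split_plan",
    "run_cv_grid",
    "summarize_cv_grid",
    "find_optimum",
    "run_pool_prediction",
    "run_scenarios",
    "POOL_DESIGNS",
    "SCENARIO_GROUPS",
]

POOL_DESIGNS = ("An+M->An+M", "An+M->An", "An+M->M", "An->An", "M->M")
SCENARIO_GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8")

ALL_SNPS = "all"


@dataclass
class CVDesign:
    """Cross-validation grid design.

    Defaults mirror the reference analysis: seven population fractions,
    eleven marker counts (the ``"all"`` sentinel resolves to the available
    marker count at run time), ten folds, 100 replicates.
    """

    folds: int = 10
    reps: int = 100
    population_fractions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0)
    snp_counts: tuple = (100, 500, 1000, 1500, 2000, 3000, 4000, 5000, 6000, 7000, ALL_SNPS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.reps < 1:
            raise ValueError("need at least 1 replicate")
        if any(not 0.0 < f <= 1.0 for f in self.population_fractions):
            raise ValueError("population fractions must lie in (0, 1]")
        for c in self.snp_counts:
            if c != ALL_SNPS and (not isinstance(c, (int, np.integer)) or c <= 0):
                raise ValueError(f"snp count must be positive or '{ALL_SNPS}', got {c!r}")


@dataclass
class SplitPlan:
    """Half-splits of the breeding lines used by the G1-G8 scenarios.

    ``a1/a2`` and ``m1/m2`` are the per-pool random halves (A1 and M1 serve
    as additional training sets, A2 and M2 as testing sets); ``rand_add`` /
    ``rand_test`` is the pooled random split of the same total size for the
    by-pool versus random comparison, drawn from the same seeded stream so
    the comparison is paired.
    """

    a1: list[str]
    a2: list[str]
    m1: list[str]
    m2: list[str]
    rand_add: list[str]
    rand_test: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.a1) & set(self.a2) or set(self.m1) & set(self.m2):
            raise ValueError("pool halves must be disjoint")
        if set(self.rand_add) & set(self.rand_test):
            raise ValueError("random halves must be disjoint")


@dataclass
class OptimumConfig:
    """The (opt_pop, opt_snp) cell chosen for one trait."""

    trait: str
    opt_pop: float
    opt_snp: int
    mean_r: float


def _check_metadata(metadata: pd.DataFrame) -> None:
    for col in ("accession_id", "pool", "class"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks column {col!r}")


def make_split_plan(
    metadata: pd.DataFrame,
    seed: int = 0,
) -> SplitPlan:
    """Randomly halve each pool's breeding lines (and all breeding lines).

    Each pool's breeding lines are shuffled and split into halves of sizes
    floor(n/2) (the additional-training half) and ceil(n/2); the pooled
    random split for the by-pool versus random comparison is drawn next
    from the same seeded stream.  Reproducible given (metadata, seed).
    """
    _check_metadata(metadata)
    breeding = metadata[metadata["class"] == "breeding"]
    if breeding.empty:
        raise ValueError("no breeding lines in the metadata")
    rng = np.random.default_rng(seed)

    halves: dict[str, tuple[list[str], list[str]]] = {}
    for pool in ("Andean", "Mesoamerican"):
        ids = breeding.loc[breeding["pool"] == pool, "accession_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"need at least 2 breeding lines in the {pool} pool")
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        halves[pool] = (
            [ids[i] for i in perm[:half]],
            [ids[i] for i in perm[half:]],
        )

    all_ids = breeding["accession_id"].tolist()
    perm = rng.permutation(len(all_ids))
    half = len(all_ids) // 2
    return SplitPlan(
        a1=halves["Andean"][0],
        a2=halves["Andean"][1],
        m1=halves["Mesoamerican"][0],
        m2=halves["Mesoamerican"][1],
        rand_add=[all_ids[i] for i in perm[:half]],
        rand_test=[all_ids[i] for i in perm[half:]],
        seed=seed,
    )


def _as_trait_frame(phenotypes, accession_ids: list[str]) -> pd.DataFrame:
    """Accept a vector, dict of vectors or DataFrame of trait values."""
    if isinstance(phenotypes, pd.DataFrame):
        frame = phenotypes.reset_index(drop=True)
    elif isinstance(phenotypes, dict):
        frame = pd.DataFrame(phenotypes)
    else:
        frame = pd.DataFrame({"trait": np.asarray(phenotypes, dtype=float)})
    if len(frame) != len(accession_ids):
        raise ValueError("phenotypes must align with the genotype accessions")
    if frame.isna().any().any():
        raise ValueError("phenotypes contain missing values")
    return frame


def _fit_design(
    G: GenotypeMatrix,
    y: pd.Series,
    train_ids: list[str],
    test_ids: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """One deterministic fit: train on train_ids, predict test_ids.

    Returns (GEBVs, observed) for the testing set.  Training (including any
    additional training set merged into ``train_ids``) and testing must be
    disjoint — overlap is a design error and raises.
    """
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"training and testing sets overlap: {sorted(overlap)[:5]} ...")
    if not test_ids:
        raise ValueError("testing set is empty")
    idx = pd.Series(np.arange(len(G.accession_ids)), index=G.accession_ids)

    enc = GenotypeEncoder().fit(G.take_accessions(train_ids))
    Z_train = enc.transform(G.take_accessions(train_ids))
    Z_test = enc.transform(G.take_accessions(test_ids))
    fit = fit_mixed_model(y.iloc[idx[train_ids].to_numpy()].to_numpy(), Z_train)
    gebv = predict_gebv(fit, Z_test)
    observed = y.iloc[idx[test_ids].to_numpy()].to_numpy()
    return gebv, observed


def _make_folds(ids: list[str], folds: int, rng: np.random.Generator) -> list[list[str]]:
    """Random partition of ids into `folds` near-equal folds."""
    if len(ids) < folds:
        raise ValueError(f"cannot make {folds} folds from {len(ids)} accessions")
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in part] for part in np.array_split(perm, folds)]


def run_cv_grid(
    G: GenotypeMatrix,
    phenotypes,
    landrace_ids: list[str],
    design: CVDesign,
) -> pd.DataFrame:
    """Replicated k-fold cross-validation over the size x marker grid.

    For each grid cell (population fraction, SNP count) and replicate: draw
    that fraction of the landraces without replacement, subsample markers
    proportionally per chromosome, partition the drawn set into folds, fit
    on folds-1 and predict the held-out fold, then compute one Pearson r on
    the replicate's pooled held-out predictions.  Returns a tidy frame with
    columns ``trait, fraction, snp_count, rep, r``; all sampling is seeded
    per (cell, replicate).
    """
    traits = _as_trait_frame(phenotypes, G.accession_ids)
    missing = set(landrace_ids) - set(G.accession_ids)
    if missing:
        raise KeyError(f"unknown landrace ids: {sorted(missing)[:5]} ...")
    if len(landrace_ids) < design.folds:
        raise ValueError("landrace set smaller than the fold count")
    idx = pd.Series(np.arange(len(G.accession_ids)), index=G.accession_ids)

    rows = []
    for ci, fraction in enumerate(design.population_fractions):
        for cj, snp_count in enumerate(design.snp_counts):
            n_snp = G.n_markers if snp_count == ALL_SNPS else int(snp_count)
            if n_snp > G.n_markers:
                raise ValueError(
                    f"snp count {n_snp} exceeds available markers {G.n_markers}"
                )
            for rep in range(design.reps):
                rng = np.random.default_rng([design.seed, ci, cj, rep])
                n_sub = max(design.folds, round(fraction * len(landrace_ids)))
                sub_ids = [
                    landrace_ids[i]
                    for i in rng.choice(len(landrace_ids), size=n_sub, replace=False)
                ]
                marker_seed = int(rng.integers(2**31 - 1))
                G_rep = subsample_markers(G, n_snp, marker_seed) if n_snp < G.n_markers else G
                folds = _make_folds(sub_ids, design.folds, rng)

                for trait in traits.columns:
                    y = traits[trait]
                    pred_all, obs_all = [], []
                    for f in range(design.folds):
                        test_ids = folds[f]
                        train_ids = [a for g, fold in enumerate(folds) if g != f for a in fold]
                        gebv, obs = _fit_design(G_rep, y, train_ids, test_ids)
                        pred_all.append(gebv)
                        obs_all.append(obs)
                    r = predictive_ability(
                        np.concatenate(pred_all), np.concatenate(obs_all)
                    )
                    rows.append((trait, fraction, snp_count, rep, r))
    return pd.DataFrame(rows, columns=["trait", "fraction", "snp_count", "rep", "r"])


def summarize_cv_grid(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Mean predictive ability per grid cell: columns trait, fraction, snp_count, mean_r."""
    return (
        per_rep.groupby(["trait", "fraction", "snp_count"], sort=False)["r"]
        .mean()
        .rename("mean_r")
        .reset_index()
    )


def find_optimum(
    grid: pd.DataFrame,
    trait: str,
    tolerance: float = 0.01,
    n_markers_all: int | None = None,
) -> OptimumConfig:
    """Cheapest grid cell on the plateau of the trait's maximum mean_r.

    Among cells whose ``mean_r >= max(mean_r) - tolerance``, returns the one
    with the smallest population fraction, then the smallest SNP count (the
    ``"all"`` sentinel resolves to ``n_markers_all`` when given, else ranks
    last).  Deterministic; an absolute-r plateau rule stands in for the
    informal "no further significant improvement" stopping criterion.
    """
    cells = grid[grid["trait"] == trait]
    if cells.empty:
        raise ValueError(f"no grid cells for trait {trait!r}")

    def snp_key(c):
        if c == ALL_SNPS:
            return n_markers_all if n_markers_all is not None else np.inf
        return int(c)

    best = cells["mean_r"].max()
    plateau = cells[cells["mean_r"] >= best - tolerance].copy()
    plateau["_snp"] = plateau["snp_count"].map(snp_key)
    row = plateau.sort_values(["fraction", "_snp"], kind="stable").iloc[0]
    opt_snp = row["snp_count"]
    return OptimumConfig(
        trait=trait,
        opt_pop=float(row["fraction"]),
        opt_snp=int(snp_key(opt_snp)) if snp_key(opt_snp) != np.inf else -1,
        mean_r=float(row["mean_r"]),
    )


def run_pool_prediction(
    G: GenotypeMatrix,
    phenotypes,
    metadata: pd.DataFrame,
    top_k: int = 30,
    top_fraction: float = 0.3,
    compute_overlap: bool = True,
) -> pd.DataFrame:
    """Landraces predicting breeding lines, pools combined and assigned.

    Five deterministic designs per trait: the combined landrace set
    predicting all breeding lines, the Andean subset and the Mesoamerican
    subset, plus each pool's landraces predicting its own breeding lines.
    Returns columns ``trait, design, r, n_train, n_test`` and, when
    ``compute_overlap``, the top-k and top-fraction overlap ratios.
    """
    _check_metadata(metadata)
    traits = _as_trait_frame(phenotypes, G.accession_ids)

    def ids(cls, pool=None):
        sel = metadata["class"] == cls
        if pool:
            sel &= metadata["pool"] == pool
        return metadata.loc[sel, "accession_id"].tolist()

    designs = {
        "An+M->An+M": (ids("landrace"), ids("breeding")),
        "An+M->An": (ids("landrace"), ids("breeding", "Andean")),
        "An+M->M": (ids("landrace"), ids("breeding", "Mesoamerican")),
        "An->An": (ids("landrace", "Andean"), ids("breeding", "Andean")),
        "M->M": (ids("landrace", "Mesoamerican"), ids("breeding", "Mesoamerican")),
    }
    rows = []
    for trait in traits.columns:
        y = traits[trait]
        for name, (train_ids, test_ids) in designs.items():
            gebv, obs = _fit_design(G, y, train_ids, test_ids)
            row = {
                "trait": trait,
                "design": name,
                "r": predictive_ability(gebv, obs),
                "n_train": len(train_ids),
                "n_test": len(test_ids),
            }
            if compute_overlap:
                k = min(top_k, len(test_ids))
                row["top_k_ratio"] = topk_overlap(gebv, obs, k=k)
                row["top_frac_ratio"] = topk_overlap(gebv, obs, fraction=top_fraction)
            rows.append(row)
    return pd.DataFrame(rows)


def scenario_groups(metadata: pd.DataFrame, plan: SplitPlan) -> dict[str, tuple[list[str], list[str]]]:
    """Training/testing id sets for the G1-G8 groups under a split plan.

    All groups train on the full landrace set; G2/G3/G5/G6/G7 add half the
    breeding lines selected by pool, G8 adds a randomly selected half.
    Returned as ``{group: (train_ids, test_ids)}`` with the additional
    training set already merged into the training ids.
    """
    _check_metadata(metadata)
    landraces = metadata.loc[metadata["class"] == "landrace", "accession_id"].tolist()
    p = plan
    return {
        "G1": (landraces, p.a2),
        "G2": (landraces + p.a1, p.a2),
        "G3": (landraces + p.a1 + p.m1, p.a2),
        "G4": (landraces, p.m2),
        "G5": (landraces + p.m1, p.m2),
        "G6": (landraces + p.a1 + p.m1, p.m2),
        "G7": (landraces + p.a1 + p.m1, p.a2 + p.m2),
        "G8": (landraces + p.rand_add, p.rand_test),
    }


def run_scenarios(
    G: GenotypeMatrix,
    phenotypes,
    metadata: pd.DataFrame,
    plan: SplitPlan,
) -> pd.DataFrame:
    """Predictive ability of the G1-G8 training-set scenarios.

    One deterministic fit per group per trait; returns columns
    ``trait, group, r, n_train, n_test``.  Training/testing overlap anywhere
    aborts with an error.
    """
    traits = _as_trait_frame(phenotypes, G.accession_ids)
    groups = scenario_groups(metadata, plan)
    rows = []
    for trait in traits.columns:
        y = traits[trait]
        for group, (train_ids, test_ids) in groups.items():
            gebv, obs = _fit_design(G, y, train_ids, test_ids)
            rows.append(
                {
                    "trait": trait,
                    "group": group,
                    "r": predictive_ability(gebv, obs),
                    "n_train": len(train_ids),
                    "n_test": len(test_ids),
                }
            )
    return pd.DataFrame(rows)
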