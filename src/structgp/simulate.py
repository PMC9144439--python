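"""Synthetic two-gene-pool germplasm cohorts with additive traits.

Emulates the statistical structure of a structured crop germplasm panel —
here modelled on common bean (*Phaseolus vulgaris*), whose accessions fall
into two strongly diverged gene pools (Andean and Mesoamerican), each
containing genetically diverse landraces and diversity-narrowed breeding
lines.  The default composition is 628 accessions: 484 landraces
(223 Andean + 261 Mesoamerican) and 144 breeding lines (60 Andean + 84
Mesoamerican) on 11 chromosomes.

Model
-----
* Each marker's ancestral allele frequency is uniform on [0.05, 0.95].
* Pool frequencies follow the Balding–Nichols model: given ancestral
  frequency ``p`` and divergence ``F`` (an Fst knob),
  ``p_pool ~ Beta(p (1-F)/F, (1-p)(1-F)/F)``.
* Accessions are fully inbred: each genotype is a single Bernoulli draw
  from its pool frequency, coded {0, 1} (the two homozygote classes).
* Breeding lines draw from allele frequencies realized in a reduced
  founder subset of their pool (drift toward each other), emulating the
  narrowed diversity of improved material.
* Markers are assigned to chromosomes in contiguous, near-equal blocks;
  markers are independent given pool frequencies (no linkage).
* Traits are purely additive: a set of QTL markers gets i.i.d. standard
  normal effects; environmental noise is scaled so the genetic fraction of
  phenotypic variance matches the requested heritability.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MARKER_MAP_COLUMNS, GenotypeMatrix, GenotypeEncoder

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "simulate_cohort",
    "simulate_phenotypes",
    "write_cohort",
    "read_phenotypes",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("accession_id", "pool", "class")

POOLS = ("Andean", "Mesoamerican")
CLASSES = ("landrace", "breeding")


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    The stratum counts default to the reference panel composition
    (223/261 landraces and 60/84 breeding lines in the Andean/Mesoamerican
    pools); ``fst`` is the Balding–Nichols divergence between the pools,
    ``founder_fraction`` the fraction of each pool's ``n_founders`` founder
    set from which breeding lines draw their allele frequencies.
    """

    n_landrace_andean: int = 223
    n_landrace_meso: int = 261
    n_breeding_andean: int = 60
    n_breeding_meso: int = 84
    n_markers: int = 10_000
    n_chromosomes: int = 11
    fst: float = 0.4
    h2: float = 0.5
    n_qtl: int = 100
    missing_rate: float = 0.0
    founder_fraction: float = 0.5
    n_founders: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_landrace_andean,
            self.n_landrace_meso,
            self.n_breeding_andean,
            self.n_breeding_meso,
        )
        if any(c < 0 for c in counts):
            raise ValueError("stratum counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one accession is required")
        if self.n_markers <= 0 or self.n_chromosomes <= 0:
            raise ValueError("n_markers and n_chromosomes must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if not 0 < self.n_qtl <= self.n_markers:
            raise ValueError("n_qtl must be in 1..n_markers")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.founder_fraction <= 1.0:
            raise ValueError("founder_fraction must lie in (0, 1]")

    @property
    def n_accessions(self) -> int:
        return (
            self.n_landrace_andean
            + self.n_landrace_meso
            + self.n_breeding_andean
            + self.n_breeding_meso
        )


@dataclass
class TraitArchitecture:
    """Realized genetic architecture of one simulated trait."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    h2: float
    genetic_values: np.ndarray = field(repr=False)


def _pool_frequencies(rng: np.random.Generator, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Balding–Nichols pool frequencies around the ancestral values."""
    if fst == 0.0:
        return p_anc.copy()
    c = (1.0 - fst) / fst
    return rng.beta(p_anc * c, (1.0 - p_anc) * c)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a genotype matrix and metadata table for one cohort.

    Returns the inbred-coded {0,1} genotype matrix (missing entries masked
    at ``config.missing_rate``) and a metadata DataFrame with columns
    ``accession_id, pool, class`` whose stratum counts equal the config's.
    Identical seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    M = config.n_markers

    p_anc = rng.uniform(0.05, 0.95, size=M)
    pool_freq = {pool: _pool_frequencies(rng, p_anc, config.fst) for pool in POOLS}

    # breeding lines draw from frequencies realized in a founder subset
    n_sub = max(1, round(config.founder_fraction * config.n_founders))
    breeding_freq = {}
    for pool in POOLS:
        founders = rng.random((n_sub, M)) < pool_freq[pool]
        breeding_freq[pool] = founders.mean(axis=0)

    strata = [
        ("Andean", "landrace", config.n_landrace_andean, "AL"),
        ("Mesoamerican", "landrace", config.n_landrace_meso, "ML"),
        ("Andean", "breeding", config.n_breeding_andean, "AB"),
        ("Mesoamerican", "breeding", config.n_breeding_meso, "MB"),
    ]
    blocks: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str]] = []
    for pool, cls, n, prefix in strata:
        freq = pool_freq[pool] if cls == "landrace" else breeding_freq[pool]
        blocks.append((rng.random((n, M)) < freq).astype(float))
        meta_rows.extend((f"{prefix}{i + 1:03d}", pool, cls) for i in range(n))

    values = np.vstack([b for b in blocks if b.shape[0]])
    if config.missing_rate > 0.0:
        values[rng.random(values.shape) < config.missing_rate] = np.nan

    # contiguous near-equal chromosome blocks; positions increase within each
    bounds = np.linspace(0, M, config.n_chromosomes + 1).round().astype(int)
    chrom = np.empty(M, dtype=object)
    pos = np.empty(M, dtype=int)
    for c in range(config.n_chromosomes):
        lo, hi = bounds[c], bounds[c + 1]
        chrom[lo:hi] = f"Chr{c + 1:02d}"
        pos[lo:hi] = 1000 * (np.arange(hi - lo) + 1)
    ref = np.where(rng.random(M) < 0.5, "A", "C")
    alt = np.where(ref == "A", "G", "T")
    marker_map = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt},
        columns=list(MARKER_MAP_COLUMNS),
    )

    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    G = GenotypeMatrix(
        values=values,
        marker_map=marker_map,
        accession_ids=metadata["accession_id"].tolist(),
    )
    return G, metadata


def simulate_phenotypes(
    G: GenotypeMatrix,
    h2: float,
    n_qtl: int,
    seed: int,
) -> tuple[np.ndarray, TraitArchitecture]:
    """Simulate one additive trait on an existing cohort.

    QTL markers are sampled uniformly among markers with at least one
    non-missing call; effects are i.i.d. standard normal on the
    mean-imputed, mean-centred genotypes (so a missing QTL call contributes
    the population mean, i.e. zero on the centred scale).  Environmental
    noise is scaled against the *realized* genetic variance so that
    var(g)/var(y) = h2 in expectation; ``h2=1`` returns the genetic values
    exactly and ``h2=0`` pure unit-variance noise.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    if not 0 < n_qtl <= G.n_markers:
        raise ValueError("n_qtl must be in 1..n_markers")
    rng = np.random.default_rng(seed)

    usable = np.flatnonzero(~np.all(np.isnan(G.values), axis=0))
    if usable.size < n_qtl:
        raise ValueError(
            f"only {usable.size} markers have any non-missing call; "
            f"cannot place {n_qtl} QTLs"
        )
    qtl = np.sort(rng.choice(usable, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)

    Zq = GenotypeEncoder().fit_transform(G.take_markers(qtl))
    g = Zq @ effects

    var_g = float(np.var(g))
    if h2 == 0.0 or var_g == 0.0:
        y = rng.standard_normal(G.n_accessions)
        g = np.zeros_like(y) if h2 == 0.0 else g
    elif h2 == 1.0:
        y = g.copy()
    else:
        sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
        y = g + rng.normal(0.0, sd_e, size=G.n_accessions)

    arch = TraitArchitecture(qtl_indices=qtl, qtl_effects=effects, h2=h2, genetic_values=g)
    return y, arch


def _format_gt(v: float) -> str:
    if np.isnan(v):
        return "./."
    return "0/0" if v == 0 else "1/1"


def write_cohort(
    G: GenotypeMatrix,
    metadata: pd.DataFrame,
    phenotypes: pd.DataFrame | dict | None,
    vcf_path: str | os.PathLike,
    pheno_path: str | os.PathLike,
) -> None:
    """Write a cohort as a minimal VCF 4.2 plus a phenotype/metadata TSV.

    The VCF carries a GT-only FORMAT with inbred genotypes ``0/0`` / ``1/1``
    and missing calls as ``./.``; reading it back reproduces the genotype
    matrix exactly, including the missing mask.  The TSV has columns
    ``accession_id  pool  class  <trait> ...``.
    """
    if G.dosage_scale != 1:
        raise ValueError("write_cohort only writes inbred {0,1}-coded matrices")
    if list(metadata["accession_id"]) != G.accession_ids:
        raise ValueError("metadata accession order must match the genotype matrix")

    contigs = pd.unique(G.marker_map["chrom"])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=structgp\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        mm = G.marker_map
        for j in range(G.n_markers):
            gts = "\t".join(_format_gt(v) for v in G.values[:, j])
            fh.write(
                f"{mm.chrom.iloc[j]}\t{mm.pos.iloc[j]}\t"
                f"{mm.chrom.iloc[j]}_{mm.pos.iloc[j]}\t"
                f"{mm.ref.iloc[j]}\t{mm.alt.iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    table = metadata.copy()
    if phenotypes is not None:
        pheno = pd.DataFrame(phenotypes)
        if len(pheno) != G.n_accessions:
            raise ValueError("phenotype length must equal the accession count")
        for col in pheno.columns:
            table[col] = np.asarray(pheno[col])
    table.to_csv(pheno_path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phenotype/metadata TSV written by :func:`write_cohort`.

    Returns ``(metadata, phenotypes)``: the ``accession_id, pool, class``
    columns and the remaining (trait) columns, index-aligned.
    """
    table = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    meta = table[list(METADATA_COLUMNS)].copy()
    traits = table.drop(columns=list(METADATA_COLUMNS))
    return meta, traits
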