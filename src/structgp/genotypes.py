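"""Genotype matrices: VCF input, marker filtering, proportional subsampling, encoding.

The central container is :class:`GenotypeMatrix`, an accessions x markers
dosage matrix for inbred material coded {0, 1} (the two homozygote classes;
``NaN`` marks missing calls), together with a marker map and ordered
accession ids.  Heterozygous calls can optionally be carried as {0, 1, 2}
dosages for outbred data (``dosage_scale = 2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "filter_markers",
    "subsample_markers",
    "largest_remainder_quotas",
    "GenotypeEncoder",
    "impute_and_encode",
]

MARKER_MAP_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with marker map and missing mask.

    Parameters
    ----------
    values
        Float array of shape ``(n_accessions, n_markers)``; entries in
        ``{0, 1}`` (or ``{0, 1, 2}`` when ``dosage_scale == 2``) with
        ``NaN`` for missing calls.
    marker_map
        DataFrame with columns ``chrom, pos, ref, alt``, one row per marker,
        positions non-decreasing within each chromosome.
    accession_ids
        Ordered unique accession identifiers, one per row.
    dosage_scale
        Maximum dosage value: 1 for inbred {0,1} coding, 2 for {0,1,2}.
    """

    values: np.ndarray
    marker_map: pd.DataFrame
    accession_ids: list[str]
    dosage_scale: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D accessions x markers array")
        if len(self.marker_map) != self.values.shape[1]:
            raise ValueError(
                f"marker_map has {len(self.marker_map)} rows for "
                f"{self.values.shape[1]} marker columns"
            )
        if len(self.accession_ids) != self.values.shape[0]:
            raise ValueError("accession_ids length must equal the row count")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids must be unique")
        missing = set(MARKER_MAP_COLUMNS) - set(self.marker_map.columns)
        if missing:
            raise ValueError(f"marker_map lacks columns {sorted(missing)}")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.values) & ~np.isin(
                self.values, np.arange(self.dosage_scale + 1)
            )
        if bad.any():
            raise ValueError(
                f"genotype values must lie in 0..{self.dosage_scale} or NaN"
            )

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a call is missing."""
        return np.isnan(self.values)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving the given order."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index],
            marker_map=self.marker_map.iloc[index].reset_index(drop=True),
        )

    def take_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Row subset by accession id, in the order given."""
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            index = [pos[a] for a in ids]
        except KeyError as exc:
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from None
        return replace(
            self,
            values=self.values[index],
            accession_ids=list(ids),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.values, axis=0) / self.dosage_scale


@dataclass
class FilterReport:
    """Counts from one marker-filtering pass.

    ``n_retained = n_input - |failed MAF ∪ failed missingness|``; a marker
    can fail both criteria, so the failure counts may sum to more than
    ``n_input - n_retained``.
    """

    n_input: int
    n_failed_maf: int
    n_failed_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_failed_maf, self.n_failed_missing, self.n_retained) < 0:
            raise ValueError("filter counts must be non-negative")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_failed_maf": self.n_failed_maf,
            "n_failed_missing": self.n_failed_missing,
            "n_retained": self.n_retained,
        }


def read_vcf(
    path: str,
    het_policy: str = "missing",
    multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a GT-field VCF into a :class:`GenotypeMatrix`.

    Diploid calls are collapsed to dosages: ``0/0 -> 0``, ``1/1 -> 1``,
    ``./. -> NaN``.  Heterozygous calls are controlled by ``het_policy``:

    ``"missing"`` (default)
        treat ``0/1`` as missing — appropriate for highly selfing, inbred
        material where residual heterozygosity is usually a genotyping
        artefact;
    ``"dosage"``
        code ``{0/0, 0/1, 1/1}`` as ``{0, 1, 2}`` alt-allele dosages
        (``dosage_scale = 2``).

    Multiallelic records raise by default (``multiallelic="error"``) or are
    dropped with ``multiallelic="skip"``.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "dosage"):
        raise ValueError("het_policy must be 'missing' or 'dosage'")
    if multiallelic not in ("error", "skip"):
        raise ValueError("multiallelic must be 'error' or 'skip'")

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")

    columns: list[np.ndarray] = []
    rows: list[tuple] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(
                    f"{path}: multiallelic record at {variant.CHROM}:{variant.POS}"
                )
            continue
        gts = np.asarray(variant.genotypes, dtype=object)
        col = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(gts):
            a, b = int(gt[0]), int(gt[1])
            if a < 0 or b < 0:
                col[i] = np.nan
            elif a == b:
                col[i] = float(a) * (2 if het_policy == "dosage" else 1)
            else:  # heterozygous
                col[i] = 1.0 if het_policy == "dosage" else np.nan
        columns.append(col)
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))

    n = len(samples)
    values = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=float)
    )
    marker_map = pd.DataFrame(rows, columns=list(MARKER_MAP_COLUMNS))
    return GenotypeMatrix(
        values=values,
        marker_map=marker_map,
        accession_ids=samples,
        dosage_scale=2 if het_policy == "dosage" else 1,
    )


def filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.50,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers by minor-allele frequency and missingness.

    A marker is retained iff its MAF is *strictly above* ``maf_min`` and its
    missing fraction is *strictly below* ``max_missing`` (both criteria
    evaluated jointly on the input, as simultaneous VCFtools-style flags).
    MAF is computed over non-missing calls only.  Column order is preserved.
    """
    if G.n_accessions == 0:
        raise ValueError("cannot filter a matrix with zero accessions")
    freq = G.allele_frequencies()
    maf = np.fmin(freq, 1.0 - freq)  # fmin: NaN freq (all-missing) -> NaN
    maf = np.where(np.isnan(maf), 0.0, maf)
    missing_frac = G.missing_mask.mean(axis=0)

    fail_maf = maf <= maf_min
    fail_missing = missing_frac >= max_missing
    keep = ~(fail_maf | fail_missing)

    report = FilterReport(
        n_input=G.n_markers,
        n_failed_maf=int(fail_maf.sum()),
        n_failed_missing=int(fail_missing.sum()),
        n_retained=int(keep.sum()),
    )
    return G.take_markers(np.flatnonzero(keep)), report


def largest_remainder_quotas(counts: Sequence[int], target: int) -> np.ndarray:
    """Apportion ``target`` among groups proportionally to ``counts``.

    Largest-remainder (Hamilton) apportionment: each group gets the floor of
    its exact proportional share, and the remaining units go to the groups
    with the largest fractional parts (ties broken toward the group with the
    larger count, then by group order).  Quotas sum exactly to ``target``
    and never exceed the group counts.
    """
    counts = np.asarray(counts, dtype=int)
    total = counts.sum()
    if not 0 < target <= total:
        raise ValueError(f"target {target} must be in 1..{total}")
    exact = target * counts / total
    quotas = np.floor(exact).astype(int)
    remainder = target - quotas.sum()
    if remainder:
        frac = exact - quotas
        # lexicographic tie-break: fractional part desc, count desc, index asc
        order = sorted(range(len(counts)), key=lambda i: (-frac[i], -counts[i], i))
        for i in order[:remainder]:
            quotas[i] += 1
    # proportional shares never round a quota above the group size, but be safe
    assert (quotas <= counts).all() and quotas.sum() == target
    return quotas


def subsample_markers(G: GenotypeMatrix, target_n: int, seed: int) -> GenotypeMatrix:
    """Sample ``target_n`` markers proportionally across chromosomes.

    Per-chromosome quotas come from largest-remainder apportionment of
    ``target_n`` by chromosome marker counts (so quotas sum exactly to
    ``target_n``); markers are then drawn uniformly without replacement
    within each chromosome.  The original column order is preserved in the
    output.  Only the within-chromosome draw is random; the quotas are a
    deterministic function of ``(counts, target_n)``.
    """
    if not 0 < target_n <= G.n_markers:
        raise ValueError(
            f"target_n {target_n} must be in 1..{G.n_markers} (available markers)"
        )
    chroms = G.marker_map["chrom"].to_numpy()
    chrom_order = pd.unique(chroms)
    counts = np.array([(chroms == c).sum() for c in chrom_order])
    quotas = largest_remainder_quotas(counts, target_n)

    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c, q in zip(chrom_order, quotas):
        idx = np.flatnonzero(chroms == c)
        if q:
            chosen.append(rng.choice(idx, size=q, replace=False))
    index = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)
    return G.take_markers(index)


class GenotypeEncoder:
    """Mean-impute and mean-centre genotypes on a training-set scale.

    ``fit`` records each marker's non-missing mean on the training
    accessions; ``transform`` replaces missing calls with that mean and
    subtracts it, so imputed cells become exactly 0 and test-set accessions
    are encoded on the training scale.
    """

    def __init__(self) -> None:
        self.column_means_: np.ndarray | None = None

    def fit(self, G: GenotypeMatrix | np.ndarray) -> "GenotypeEncoder":
        values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
        n_obs = (~np.isnan(values)).sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError(
                "marker with zero non-missing training calls; "
                "filter markers on missingness before encoding"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.column_means_ = np.nanmean(values, axis=0)
        return self

    def transform(self, G: GenotypeMatrix | np.ndarray) -> np.ndarray:
        if self.column_means_ is None:
            raise RuntimeError("encoder is not fitted")
        values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
        if values.shape[1] != self.column_means_.size:
            raise ValueError(
                f"matrix has {values.shape[1]} markers, encoder was fitted on "
                f"{self.column_means_.size}"
            )
        Z = values - self.column_means_
        np.copyto(Z, 0.0, where=np.isnan(Z))
        return Z

    def fit_transform(self, G: GenotypeMatrix | np.ndarray) -> np.ndarray:
        return self.fit(G).transform(G)


def impute_and_encode(G: GenotypeMatrix) -> tuple[np.ndarray, GenotypeEncoder]:
    """Encode a (filtered) genotype matrix for the mixed model.

    Returns the imputed, column-centred model matrix ``Z`` and the fitted
    encoder, whose centring constants must be reused to encode any test-set
    accessions on the training scale.
    """
    enc = GenotypeEncoder()
    return enc.fit_transform(G), enc
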