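"""Principal-component analysis of genotype matrices for population structure.

PCA of the column-centred (not variance-scaled) genotype matrix, the
population-genetics default: component geometry then reflects
allele-frequency divergence, and diverged gene pools appear as separated
clusters in the leading components.  A silhouette-based separation score
quantifies how cleanly a given pool labelling splits in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix, GenotypeEncoder

__all__ = ["PCAResult", "compute_pca", "pool_separation"]


@dataclass
class PCAResult:
    """Scores, loadings and per-component explained variance fractions.

    ``explained_fraction`` is each retained component's share of the *total*
    variance, so the retained fractions are non-increasing and sum to at
    most 1 (exactly 1 over all ``min(N-1, M)`` components).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray

    @property
    def component_count(self) -> int:
        return self.scores.shape[1]


def compute_pca(
    G: GenotypeMatrix | np.ndarray,
    n_components: int = 3,
) -> PCAResult:
    """PCA of a genotype matrix via singular value decomposition.

    Accepts a :class:`GenotypeMatrix` (mean-imputed and centred internally)
    or an already-encoded numeric array (re-centred, which is idempotent on
    encoded input).  Scores are ``U S`` for the top components.  The result
    is deterministic: each component's sign is fixed by forcing its
    largest-magnitude marker loading positive.
    """
    if isinstance(G, GenotypeMatrix):
        Z = GenotypeEncoder().fit_transform(G)
    else:
        Z = np.asarray(G, dtype=float)
        if np.isnan(Z).any():
            raise ValueError("encoded matrix must carry no missing values")
        Z = Z - Z.mean(axis=0)
    n, m = Z.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 accessions")
    max_rank = min(n - 1, m)
    if not 0 < n_components <= max_rank:
        raise ValueError(f"n_components must be in 1..{max_rank}")

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((s**2).sum())
    explained = s[:n_components] ** 2 / total if total > 0 else np.zeros(n_components)

    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(scores=scores, loadings=loadings, explained_fraction=explained)


def pool_separation(
    scores: np.ndarray,
    labels: Sequence,
    n_components: int = 3,
) -> float:
    """Silhouette coefficient of a pool labelling in PC space.

    Computed on the first ``n_components`` score columns (or all available,
    if fewer); returns a value in [-1, 1], near 1 for cleanly separated
    pools and near 0 when the labelling is no better than chance.
    """
    from sklearn.metrics import silhouette_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.size:
        raise ValueError("scores and labels must align")
    if np.unique(labels).size < 2:
        raise ValueError("separation needs at least two pools in the labelling")
    k = min(n_components, scores.shape[1])
    return float(silhouette_score(scores[:, :k], labels))
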