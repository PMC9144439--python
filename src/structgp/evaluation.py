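"""Evaluation statistics for genomic prediction.

Two statistics: *predictive ability*, the Pearson correlation between
predicted (GEBV) and observed phenotypes in a testing set, averaged over
replicates when a design is replicated; and the *top-k overlap ratio*, the
fraction of the top-k accessions by predicted value that are also top-k by
observed value — the quantity a breeder selecting the best candidates
actually cares about (reported both for a fixed k, e.g. 30, and for a
fraction of the testing set, e.g. the top 30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PredictionResult", "predictive_ability", "topk_overlap"]


@dataclass
class PredictionResult:
    """Per-replicate correlations and overlap ratios for one design."""

    per_rep_r: list[float]
    n_test: int
    top_k_ratio: float | None = None
    top_frac_ratio: float | None = None

    @property
    def mean_r(self) -> float:
        """Predictive ability: the arithmetic mean of per-replicate r."""
        return float(np.mean(self.per_rep_r))


def predictive_ability(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation between predicted and observed values.

    Raises rather than silently dropping on NaN inputs, length mismatch,
    fewer than 3 pairs, or zero variance in either vector.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.isnan(predicted).any() or np.isnan(observed).any():
        raise ValueError("inputs contain NaN")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("zero variance in predicted or observed values")
    return float(stats.pearsonr(predicted, observed).statistic)


def _top_indices(values: np.ndarray, k: int, direction: str) -> set[int]:
    # stable sort: ties resolved by original (accession) order
    key = -values if direction == "descending" else values
    return set(np.argsort(key, kind="stable")[:k].tolist())


def topk_overlap(
    predicted: np.ndarray,
    observed: np.ndarray,
    k: int | None = None,
    fraction: float | None = None,
    direction: str = "descending",
) -> float:
    """Overlap ratio of the top-k sets by predicted and by observed value.

    Exactly one of ``k`` and ``fraction`` must be given; a fraction is
    converted to ``k = round(fraction * n)`` (half away from zero, minimum
    1).  ``direction`` says whether larger values are better
    (``"descending"``, the default) or smaller (``"ascending"``, e.g.
    days-to-flowering).  Ties are broken by stable input order.  The ratio
    lies in [0, 1]; under independent rankings its expectation is ``k/n``.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    n = predicted.size
    if n == 0:
        raise ValueError("empty vectors")
    if direction not in ("descending", "ascending"):
        raise ValueError("direction must be 'descending' or 'ascending'")
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k and fraction")
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        k = max(1, int(np.floor(fraction * n + 0.5)))
    if not 0 < k <= n:
        raise ValueError(f"k must be in 1..{n}")

    top_pred = _top_indices(predicted, k, direction)
    top_obs = _top_indices(observed, k, direction)
    return len(top_pred & top_obs) / k
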