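"""Independent oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def hudson_fst(values_pop1: np.ndarray, values_pop2: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio-of-averages) for haploid-coded {0,1} calls.

    Written directly from the estimator's definition — unbiased per-locus
    numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) over denominator
    p1(1-p2) + p2(1-p1), averaged as a ratio of sums across loci.
    """
    p1 = np.nanmean(values_pop1, axis=0)
    p2 = np.nanmean(values_pop2, axis=0)
    n1 = (~np.isnan(values_pop1)).sum(axis=0)
    n2 = (~np.isnan(values_pop2)).sum(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def pearson_by_hand(x, y) -> float:
    """Closed-form sample Pearson r from its definition, no library call."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.sum() / x.size
    dy = y - y.sum() / y.size
    return float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))


def gblup_predictions(y, Z_train, Z_test, lam) -> np.ndarray:
    """Kernel (GBLUP) form of the ridge prediction at a given variance ratio.

    GEBV_test = K_test,train (K_train + lam I)^-1 (y - X beta_GLS), the
    algebraic mirror of the marker-effect formulation.
    """
    n = len(y)
    K = Z_train @ Z_train.T
    H = K + lam * np.eye(n)
    Hinv = np.linalg.inv(H)
    X = np.ones((n, 1))
    beta = np.linalg.solve(X.T @ Hinv @ X, X.T @ Hinv @ y)
    return (Z_test @ Z_train.T) @ Hinv @ (y - X @ beta)


def reml_grid_argmax(profile, lo=-8.0, hi=8.0, points=401) -> tuple[float, float]:
    """Brute-force REML grid search; returns (log-lambda at argmax, step)."""
    grid = np.linspace(lo, hi, points)
    ll = profile(grid)
    return float(grid[int(np.argmax(ll))]), float(grid[1] - grid[0])
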