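"""RR-BLUP mixed model with REML variance components.

Fits the single-random-effect model

    y = X beta + Z u + e,   u ~ N(0, I sigma_u^2),   e ~ N(0, I sigma_e^2)

where ``y`` holds the training phenotypes, ``X`` the fixed-effect design
(an intercept column by default) and ``Z`` the encoded (imputed,
column-centred) genotype matrix.  Variance components are estimated by
restricted maximum likelihood over the single ratio
``lambda = sigma_e^2 / sigma_u^2``, using the spectral decomposition of
the genomic kernel ``K = Z Z'`` restricted to the orthogonal complement of
``col(X)`` — so each likelihood evaluation is O(N) after one O(N^3)
decomposition.  At the optimum, ``beta`` is the GLS estimate and the
marker-effect BLUPs are

    u = Z' (K + lambda I)^{-1} (y - X beta),

the ridge solution with penalty ``lambda``; genomic estimated breeding
values (GEBVs) for new material are ``Z_test u`` on the centred scale.
This marker-effect formulation is algebraically identical to the kernel
(GBLUP) formulation, which the test-suite exploits as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, qr
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "fit_mixed_model", "predict_gebv", "reml_profile"]

# search bracket for log(lambda); solutions clamped here are flagged boundary
LOG_LAMBDA_BOUNDS = (-10.0, 10.0)
_GRID_POINTS = 101


@dataclass
class MixedModelFit:
    """Result of one REML RR-BLUP fit.

    ``var_u``/``var_e`` are the marker-effect and residual variances,
    ``lambda_`` their ratio ``var_e/var_u``, ``reml_loglik`` the restricted
    log-likelihood at the optimum.  ``boundary`` flags a fit clamped at the
    edge of the lambda search bracket (effectively no genetic or no
    residual variance).
    """

    beta: np.ndarray
    u: np.ndarray
    var_u: float
    var_e: float
    lambda_: float
    reml_loglik: float
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.var_u < 0 or self.var_e < 0:
            raise ValueError("variance components must be non-negative")


def _restricted_loglik(log_lambda: np.ndarray | float, xi: np.ndarray, eta2: np.ndarray) -> np.ndarray | float:
    """Profiled REML log-likelihood at ratio lambda = exp(log_lambda).

    ``xi`` are the eigenvalues of the kernel restricted to the complement of
    the fixed-effect space; ``eta2`` the squared rotated responses.
    """
    lam = np.exp(np.atleast_1d(log_lambda))[:, None]
    nq = xi.size
    denom = xi[None, :] + lam
    r = (eta2[None, :] / denom).sum(axis=1)
    ll = 0.5 * (
        nq * (np.log(nq / (2.0 * np.pi)) - 1.0 - np.log(r))
        - np.log(denom).sum(axis=1)
    )
    return ll if np.ndim(log_lambda) else float(ll[0])


def reml_profile(y: np.ndarray, Z: np.ndarray, X: np.ndarray | None = None):
    """Return the profiled REML log-likelihood as a function of log(lambda).

    Exposed for diagnostics and for grid-search cross-checks of the solver.
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    n = y.size
    X = np.ones((n, 1)) if X is None else np.asarray(X, float)
    xi, eta2 = _restrict(y, Z, X)
    return lambda log_lambda: _restricted_loglik(log_lambda, xi, eta2)


def _restrict(y: np.ndarray, Z: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the model into the orthogonal complement of col(X)."""
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("fixed-effect design X is rank deficient")
    Q, _ = qr(X, mode="full")
    Q2 = Q[:, q:]  # orthonormal basis of the complement, n x (n - q)
    K = Z @ Z.T
    xi, vecs = eigh(Q2.T @ K @ Q2)
    xi = np.clip(xi, 0.0, None)
    eta = vecs.T @ (Q2.T @ y)
    return xi, eta**2


def fit_mixed_model(
    y: np.ndarray,
    Z: np.ndarray,
    X: np.ndarray | None = None,
) -> MixedModelFit:
    """REML fit of the RR-BLUP model; see the module docstring for the model.

    Parameters
    ----------
    y
        Training phenotypes, length N >= 3, no missing values.
    Z
        N x M encoded genotype matrix (imputed and column-centred on the
        training scale; {0,1} inbred or {0,1,2} dosages both accepted).
    X
        Fixed-effect design, default a single intercept column.

    The variance ratio is found by a coarse grid over
    ``log lambda in [-10, 10]`` refined by bounded Brent search (tolerance
    1e-8 on log lambda); a ratio clamped at the bracket edge is flagged
    ``boundary=True`` rather than an error.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D vector")
    n = y.size
    if Z.ndim != 2 or Z.shape[0] != n:
        raise ValueError(f"Z must be 2-D with {n} rows, got shape {Z.shape}")
    if n < 3:
        raise ValueError("need at least 3 training observations")
    if Z.shape[1] < 1:
        raise ValueError("need at least one marker")
    if not (np.isfinite(y).all() and np.isfinite(Z).all()):
        raise ValueError("inputs contain non-finite values")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("X must be 2-D with one row per observation")
    q = X.shape[1]
    if n - q < 2:
        raise ValueError("too few residual degrees of freedom")

    K = Z @ Z.T

    # degenerate inputs: no representable genetic signal -> OLS boundary fit
    if np.trace(K) <= 1e-12 or np.var(y) == 0.0:
        if np.var(y) == 0.0:
            warnings.warn("phenotype has zero variance; returning boundary fit")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        var_e = float(resid @ resid) / (n - q)
        return MixedModelFit(
            beta=beta,
            u=np.zeros(Z.shape[1]),
            var_u=0.0,
            var_e=var_e,
            lambda_=np.inf,
            reml_loglik=np.nan,
            boundary=True,
        )

    xi, eta2 = _restrict(y, Z, X)

    lo, hi = LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    ll = _restricted_loglik(grid, xi, eta2)
    i = int(np.argmax(ll))
    res = minimize_scalar(
        lambda t: -_restricted_loglik(t, xi, eta2),
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, _GRID_POINTS - 1)]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x)
    boundary = i in (0, _GRID_POINTS - 1)
    lam = float(np.exp(log_lam))
    loglik = _restricted_loglik(log_lam, xi, eta2)

    var_u = float((eta2 / (xi + lam)).sum() / (n - q))
    var_e = lam * var_u

    # GLS fixed effects and ridge-equivalent marker BLUPs at the optimum
    Hc = cho_factor(K + lam * np.eye(n), lower=True)
    HinvX = cho_solve(Hc, X)
    Hinvy = cho_solve(Hc, y)
    beta = np.linalg.solve(X.T @ HinvX, X.T @ Hinvy)
    u = Z.T @ cho_solve(Hc, y - X @ beta)

    return MixedModelFit(
        beta=beta,
        u=u,
        var_u=var_u,
        var_e=var_e,
        lambda_=lam,
        reml_loglik=loglik,
        boundary=boundary,
    )


def predict_gebv(
    fit: MixedModelFit,
    Z_test: np.ndarray,
    include_fixed: bool = False,
    X_test: np.ndarray | None = None,
) -> np.ndarray:
    """Genomic estimated breeding values for encoded test genotypes.

    ``Z_test`` must be encoded with the *training* centring constants and
    have the fit's marker count.  The default returns the additive genetic
    value ``Z_test u`` on the centred scale (predictive ability is invariant
    to the intercept); ``include_fixed=True`` adds ``X_test beta``
    (intercept-only when ``X_test`` is omitted) for phenotype-scale output.
    """
    Z_test = np.asarray(Z_test, dtype=float)
    if Z_test.ndim != 2 or Z_test.shape[1] != fit.u.size:
        raise ValueError(
            f"Z_test must have {fit.u.size} marker columns, got shape {Z_test.shape}"
        )
    gebv = Z_test @ fit.u
    if include_fixed:
        if X_test is None:
            X_test = np.ones((Z_test.shape[0], fit.beta.size))
            if fit.beta.size != 1:
                raise ValueError("X_test required for non-intercept fixed effects")
        gebv = gebv + np.asarray(X_test, float) @ fit.beta
    return gebv
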