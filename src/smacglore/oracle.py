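"""Double-precision reference fits and the statistics reported alongside them.

This module is the statistical yardstick for the secure pipeline: ordinary
logistic regression by Newton–Raphson (IRLS), the fixed-Hessian variant in
floating point, Wald tests, the two-sample Z test used to compare
coefficients across fitting methods, and MSE utilities.  Standard errors
and p-values are computed here, never inside the secure computation, which
releases coefficients only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass
class OracleFit:
    beta: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    converged: bool
    iterations: int


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def log_likelihood(X, y, beta) -> float:
    """Standard logistic log-likelihood sum(y*xb - log(1 + e^xb))."""
    xb = np.asarray(X) @ np.asarray(beta)
    return float(np.sum(np.asarray(y) * xb - np.logaddexp(0.0, xb)))


def _covariance(X, beta):
    p = _logistic(X @ beta)
    W = p * (1.0 - p)
    H = X.T @ (W[:, None] * X)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularDesignError(
            f"information matrix condition number {cond:.3g}")
    return np.linalg.inv(H)


def fit_irls(X, y, tol: float = 1e-8, max_iter: int = 50) -> OracleFit:
    """Newton–Raphson with the exact Hessian X'WX (IRLS).

    Converged when the largest coefficient update falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _logistic(X @ beta)
        W = p * (1.0 - p)
        H = X.T @ (W[:, None] * X)
        g = X.T @ (y - p)
        cond = np.linalg.cond(H)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularDesignError(
                f"information matrix condition number {cond:.3g} at "
                f"iteration {it}")
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    cov = _covariance(X, beta)
    return OracleFit(beta=beta, covariance=cov, se=np.sqrt(np.diag(cov)),
                     converged=converged, iterations=it)


def fit_fixed_hessian(X, y, iters: int = 100) -> OracleFit:
    """Newton updates with the constant matrix X'X/4 in place of X'WX.

    Same maximiser as IRLS (the bound dominates the true information
    matrix, so steps are conservative and monotone); linear convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    A = 0.25 * (X.T @ X)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularDesignError(f"X'X/4 condition number {cond:.3g}")
    A_inv = np.linalg.inv(A)
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        g = X.T @ (y - _logistic(X @ beta))
        beta = beta + A_inv @ g
    cov = _covariance(X, beta)
    return OracleFit(beta=beta, covariance=cov, se=np.sqrt(np.diag(cov)),
                     converged=True, iterations=iters)


def wald_stats(beta_k: float, se_k: float):
    """Wald z = beta/SE and the two-sided normal p-value."""
    if se_k <= 0:
        raise ValueError("standard error must be positive")
    z = beta_k / se_k
    return z, 2.0 * sps.norm.sf(abs(z))


def two_sample_z(beta_a: float, se_a: float, beta_b: float, se_b: float):
    """z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided p."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_a - beta_b) / np.hypot(se_a, se_b)
    return z, 2.0 * sps.norm.sf(abs(z))


def mse(A, B) -> float:
    """Mean squared elementwise difference."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    return float(np.mean((A - B) ** 2))
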