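"""Dense OLS helpers shared by the estimator modules.

Thin wrappers over numpy/scipy least squares used in hot loops where building
a statsmodels model per call would dominate runtime. Public model fits in
:mod:`genmr.mr` report identical numbers to statsmodels (tested).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy import stats


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if X is None or X.size == 0:
        return ones
    return np.hstack([ones, np.asarray(X, dtype=float)])


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the aliased columns if X is rank-deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank_qr = int((diag > tol).sum())
    aliased = sorted(names[j] for j in piv[rank_qr:])
    raise np.linalg.LinAlgError(f"design matrix is collinear; aliased columns: {aliased}")


def ols(y: np.ndarray, X: np.ndarray):
    """OLS fit returning (coef, se, rss, df_resid).

    Standard errors are the usual analytic ones, sigma^2 (X'X)^-1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design in OLS")
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the number of regressors")
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return coef, se, rss, df


def t_ci_p(beta: float, se: float, df: int, level: float = 0.95):
    """Two-sided t confidence interval and p-value."""
    if se == 0:
        return beta, beta, 0.0 if beta != 0 else 1.0
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    tstat = beta / se
    p = 2 * stats.t.sf(abs(tstat), df)
    return beta - tcrit * se, beta + tcrit * se, float(p)


def residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on X (Frisch-Waugh step)."""
    coef, _, _, _ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef
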