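"""Vectorized ordinary least squares shared by the probe-wise model fits.

One design matrix, many response vectors: coefficients, standard errors and
two-sided t-test p-values are computed for every response in a single pass of
dense linear algebra.  Rank deficiency is detected via column-pivoted QR so
offending columns can be reported (or dropped) by name.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy import stats


def aliased_columns(X: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Names of columns that are (numerically) linear combinations of earlier ones."""
    if X.shape[0] < X.shape[1]:
        return names[X.shape[0]:]
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    bad = diag < tol * scale
    return [names[piv[j]] for j in range(len(names)) if bad[j]]


def ols_fit(Y: np.ndarray, X: np.ndarray):
    """Fit Y[:, r] ~ X for every response column r.

    Parameters
    ----------
    Y : (n_obs, n_responses) response matrix
    X : (n_obs, k) full-rank design matrix

    Returns
    -------
    coef, se, t, p : (k, n_responses) arrays, and the residual df (n_obs - k).
    """
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError(f"not enough observations ({n}) for {k} design columns")
    Q, R = np.linalg.qr(X)
    coef = scipy.linalg.solve_triangular(R, Q.T @ Y)
    resid = Y - X @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    Rinv = scipy.linalg.solve_triangular(R, np.eye(k))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    # exact fits: se = 0 with non-zero coef -> infinite t (p ~ 0); 0/0 -> t = 0
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # p-values live in (0, 1]; exact fits underflow to 0, keep them positive
    p = np.maximum(p, np.finfo(float).tiny)
    return coef, se, t, p, df, sigma2, xtx_inv_diag
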