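"""Small shared statistical helpers (marginal OLS, BH q-values)."""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def marginal_ols(y: np.ndarray, X: np.ndarray):
    """Simple linear regression of ``y`` on each column of ``X`` separately.

    Returns (beta, se, t, p, valid) where ``valid`` flags columns with
    non-zero dosage variance; invalid columns carry NaN statistics.
    p-values are two-sided from the t distribution with n-2 df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    valid = sxx > 0
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(valid, sxy / sxx, np.nan)
        sse = syy - np.where(valid, sxy**2 / sxx, 0.0)
        sse = np.clip(sse, 0.0, None)
        se = np.sqrt(sse / (n - 2) / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta[~valid] = np.nan
    se[~valid] = np.nan
    t[~valid] = np.nan
    p[~valid] = np.nan
    return beta, se, t, p, valid


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Plain (unadjusted) R^2 of an OLS fit with intercept.

    Uses least squares on centered data; rank-deficient designs (e.g.
    perfectly correlated SNPs) are handled by the minimum-norm solution,
    whose fitted values -- and hence R^2 -- are still well defined.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0
    Xc = np.asarray(X, dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    return 1.0 - float(resid @ resid) / sst


def ols_fit(y: np.ndarray, X: np.ndarray):
    """OLS with intercept: returns (coef, se, t, p, r2)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    xtx = Xc.T @ Xc
    xty = Xc.T @ yc
    coef = np.linalg.solve(xtx, xty)
    resid = yc - Xc @ coef
    sse = float(resid @ resid)
    sst = float(yc @ yc)
    df = n - k - 1
    sigma2 = sse / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return coef, se, t, p, r2
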