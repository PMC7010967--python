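"""Expression filtering, TMM normalization, log-CPM, and factor residualization.

The pipeline mirrors a standard bulk RNA-seq preparation for cis-genetic
analysis: lowly expressed genes are removed with strict read/CPM
thresholds, library sizes are corrected by trimmed-mean-of-M-values (TMM)
scaling factors, counts are log2-CPM transformed with the 0.5 / +1 offsets
of the voom transform (precision weights are not computed), and known
covariates plus leading principal components of the residual expression --
stand-ins for hidden technical factors -- are regressed out.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def filter_genes(counts: pd.DataFrame, min_reads: int = 6, min_cpm: float = 1.0,
                 min_samples: int = 10) -> pd.DataFrame:
    """Keep genes with > ``min_reads`` raw counts and > ``min_cpm`` CPM in
    at least ``min_samples`` samples.  Both inequalities are strict."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    ok = (counts.to_numpy() > min_reads) & (cpm > min_cpm)
    keep = ok.sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("filter_genes removed every gene")
    return counts.loc[keep]


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference sample.

    Genes with a zero in either sample are excluded; 30% of M-values and
    5% of A-values are trimmed symmetrically; the remaining M-values are
    combined with inverse-variance (precision) weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_obs = np.log2(obs / lib_obs)
        log_ref = np.log2(ref / lib_ref)
        m = log_obs - log_ref
        a = (log_obs + log_ref) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the across-sample mean upper quartile.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with all-zero counts")
    uq = np.quantile(x / lib[None, :], 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([
        _tmm_pair_factor(x[:, j], x[:, ref], lib[j], lib[ref])
        for j in range(x.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2-CPM with voom offsets: log2((count + 0.5) / (lib * factor + 1) * 1e6)."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if factors is None:
        eff = lib
    else:
        f = factors.reindex(counts.columns).to_numpy(dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("normalization factors must be positive for all samples")
        eff = lib * f
    vals = np.log2((counts.to_numpy(dtype=float) + 0.5) / (eff[None, :] + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _check_collinear(cov: pd.DataFrame) -> None:
    x = cov.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via pivoted QR
        _q, _r, piv = qr(x, pivoting=True, mode="economic")
        bad = [cov.columns[i] for i in piv[rank:]]
        raise ValueError(f"collinear covariates: {bad}")


def remove_hidden_factors(logexpr: pd.DataFrame,
                          known_covariates: pd.DataFrame | None = None,
                          n_factors: int = 5):
    """Residualize expression on known covariates and PCA hidden factors.

    Hidden technical variation is estimated as the ``n_factors`` leading
    principal components of the covariate-residualized expression matrix
    (a projection-based stand-in for surrogate-variable estimation, which
    by construction is orthogonal to the known covariates).  Returns
    ``(residuals, factors)`` where ``factors`` is samples x n_factors.
    """
    Y = logexpr.to_numpy(dtype=float)
    G, n = Y.shape
    design = [np.ones((n, 1))]
    if known_covariates is not None and known_covariates.shape[1] > 0:
        _check_collinear(known_covariates)
        design.append(known_covariates.to_numpy(dtype=float))
    C = np.column_stack(design)
    rank_c = np.linalg.matrix_rank(C)
    if n_factors >= n - rank_c:
        raise ValueError("n_factors must be < n_samples - rank(covariates) - 1")
    # residualize on known covariates
    coef, *_ = np.linalg.lstsq(C, Y.T, rcond=None)
    R = Y.T - C @ coef  # samples x genes
    if n_factors > 0:
        # leading left-singular vectors across samples
        u, s, _vt = np.linalg.svd(R, full_matrices=False)
        factors = u[:, :n_factors] * s[:n_factors]
        design_full = np.column_stack([C, factors])
    else:
        factors = np.empty((n, 0))
        design_full = C
    coef2, *_ = np.linalg.lstsq(design_full, Y.T, rcond=None)
    resid = (Y.T - design_full @ coef2).T
    residuals = pd.DataFrame(resid, index=logexpr.index, columns=logexpr.columns)
    factors_df = pd.DataFrame(factors, index=logexpr.columns,
                              columns=[f"factor{i + 1}" for i in range(factors.shape[1])])
    return residuals, factors_df
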