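"""Sparse multi-SNP expression prediction models.

The builder follows an iterative scheme: (1) LASSO over all cis SNPs with
the penalty chosen by repeated 10-fold cross-validation (mean MSE over
repeats x folds on a shared log-spaced grid); (2) a forward filter that
re-adds selected SNPs in order of their joint-OLS p-values until 95% of
the full model's R^2 is reached, dropping perfect-LD duplicates at
random; (3) ridge smoothing of the retained SNPs with the penalty again
chosen by repeated cross-validation -- the ridge coefficients are the
final per-SNP weights; (4) a model-fit p-value from regressing observed
expression on pre-validated (out-of-fold) predictions, FDR-corrected
across all genes, with q >= 0.01 models dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from ._stats import bh_qvalues, ols_r2
from .eqtl import CisWindow
from .synthetic import GenotypePanel

logger = logging.getLogger(__name__)

DEFAULT_RIDGE_GRID = np.logspace(-2.0, 5.0, 43)


@dataclass
class BuilderProfile:
    """Cross-validation effort knobs.

    ``default()`` matches the study design (200 LASSO CV repeats, 25 ridge
    CV repeats, 10 folds, 100 penalties); ``test()`` is the scaled-down
    profile for test-sized runs, ``fast()`` for large per-seed simulations.
    """

    n_lambda: int = 100
    k: int = 10
    lasso_repeats: int = 200
    ridge_repeats: int = 25
    r2_threshold: float = 0.95

    @classmethod
    def default(cls) -> "BuilderProfile":
        return cls()

    @classmethod
    def test(cls) -> "BuilderProfile":
        return cls(lasso_repeats=20, ridge_repeats=5)

    @classmethod
    def fast(cls) -> "BuilderProfile":
        return cls(lasso_repeats=5, ridge_repeats=3)


@dataclass
class ExpressionModel:
    """Final per-gene SNP weights and fit diagnostics."""

    gene_id: str
    snp_ids: list[str]
    snp_weights: dict[str, float]
    intercept: float = 0.0
    lambda_lasso: float = np.nan
    ridge_alpha: float = np.nan
    r2_full: float = np.nan
    r2_filtered: float = np.nan
    fit_p: float = np.nan
    fit_q: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def weights_array(self) -> np.ndarray:
        return np.array([self.snp_weights[s] for s in self.snp_ids])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights_array() + self.intercept


# -- LASSO penalty selection ---------------------------------------------

def lambda_grid(X_std: np.ndarray, y_centered: np.ndarray, n_lambda: int = 100,
                decades: float = 3.0) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max = max|X'y|/n down ``decades``."""
    n = X_std.shape[0]
    lam_max = np.max(np.abs(X_std.T @ y_centered)) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def lasso_select(y: np.ndarray, X: np.ndarray, snp_ids, n_lambda: int = 100,
                 k: int = 10, repeats: int = 200, seed: int = 0):
    """Select SNPs by repeated-CV LASSO.

    Returns ``(lambda_star, selected_ids, selected_idx)``.  Constant y (or
    a penalty path that never improves on the intercept) yields an empty
    selection, i.e. the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    snp_ids = list(snp_ids)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if y.std() == 0:
        logger.warning("constant expression vector; intercept-only model")
        return np.nan, [], np.array([], dtype=int)
    sd = X.std(axis=0)
    usable = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, usable] = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    yc = y - y.mean()
    alphas = lambda_grid(Xs, yc, n_lambda)

    mse = np.zeros(n_lambda)
    k_eff = min(k, n)
    for r in range(repeats):
        kf = KFold(n_splits=k_eff, shuffle=True, random_state=seed + r)
        for tr, te in kf.split(Xs):
            Xtr = Xs[tr]
            mu = Xtr.mean(axis=0)
            Xtr = Xtr - mu
            ytr = yc[tr]
            ym = ytr.mean()
            _a, coefs, _g = lasso_path(Xtr, ytr - ym, alphas=alphas)
            pred = (Xs[te] - mu) @ coefs + ym
            mse += np.mean((pred - yc[te][:, None]) ** 2, axis=0)
    mse /= repeats * k_eff
    best = int(np.argmin(mse))  # ties: argmin takes the largest penalty first
    lam = float(alphas[best])
    _a, coefs, _g = lasso_path(Xs, yc, alphas=alphas[: best + 1])
    sel = np.flatnonzero(np.abs(coefs[:, -1]) > 0)
    return lam, [snp_ids[i] for i in sel], sel


# -- forward filter -------------------------------------------------------

def _perfect_ld_groups(X: np.ndarray, tol: float = 1e-10) -> list[list[int]]:
    """Connected components of the |r| = 1 graph over columns of X."""
    p = X.shape[1]
    r = np.corrcoef(X, rowvar=False).reshape(p, p)
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if abs(r[i, j]) >= 1.0 - tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(p):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _joint_pvalues(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Coefficient t-test p-values in the joint OLS fit (pinv-robust)."""
    n, kk = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    xtx = Xc.T @ Xc
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (Xc.T @ yc)
    resid = yc - Xc @ coef
    df = max(n - kk - 1, 1)
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 1e-300, None))
    t = coef / se
    return 2.0 * stats.t.sf(np.abs(t), df=df)


def forward_filter(y: np.ndarray, X_selected: np.ndarray, snp_ids,
                   positions=None, threshold: float = 0.95, seed: int = 0):
    """Forward re-addition of LASSO-selected SNPs up to 95% of full R^2.

    Perfect-LD groups are collapsed to one randomly retained member before
    ordering; SNPs are then added in ascending order of their joint-OLS
    p-value (single initial ordering) until the subset R^2 reaches
    ``threshold`` times the full-model R^2.

    Returns ``(kept_ids, r2_full, r2_filtered, flags)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_selected, dtype=float)
    snp_ids = list(snp_ids)
    if X.shape[1] == 0:
        raise ValueError("forward_filter needs at least one selected SNP")
    if positions is None:
        positions = np.arange(X.shape[1])
    positions = np.asarray(positions)
    flags: list[str] = []
    rng = np.random.default_rng(seed)

    r2_full = ols_r2(y, X)
    # collapse perfect-LD groups before ordering
    keep_idx = []
    for group in _perfect_ld_groups(X):
        if len(group) == 1:
            keep_idx.append(group[0])
        else:
            keep_idx.append(int(rng.choice(group)))
            flags.append("perfect_ld_collapsed")
    keep_idx = sorted(keep_idx)
    Xd = X[:, keep_idx]
    ids_d = [snp_ids[i] for i in keep_idx]
    pos_d = positions[keep_idx]

    pvals = _joint_pvalues(y, Xd)
    order = np.lexsort((pos_d, pvals))
    if r2_full <= 0:
        flags.append("zero_r2_full")
        best = order[0]
        return [ids_d[best]], r2_full, 0.0, flags

    chosen: list[int] = []
    r2_sub = 0.0
    for i in order:
        chosen.append(i)
        r2_sub = ols_r2(y, Xd[:, chosen])
        if r2_sub >= threshold * r2_full:
            break
    kept = [ids_d[i] for i in chosen]
    return kept, r2_full, r2_sub, flags


# -- ridge smoothing ------------------------------------------------------

def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Ridge coefficients on centered data for every alpha (p x n_alpha)."""
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    xty = evecs.T @ (Xc.T @ yc)
    return evecs @ (xty[:, None] / (evals[:, None] + alphas[None, :]))


def ridge_smooth(y: np.ndarray, X_subset: np.ndarray, snp_ids, k: int = 10,
                 repeats: int = 25, seed: int = 0, alphas: np.ndarray | None = None):
    """Repeated-CV ridge on the filtered SNP subset.

    Returns ``(alpha_star, weights, intercept)`` where weights are the
    full-sample ridge coefficients at the chosen penalty, in expression
    units per counted allele.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_subset, dtype=float)
    snp_ids = list(snp_ids)
    if X.shape[1] == 0:
        raise ValueError("ridge_smooth needs at least one SNP")
    if alphas is None:
        alphas = DEFAULT_RIDGE_GRID
    alphas = np.asarray(alphas, dtype=float)
    n = X.shape[0]
    yc = y - y.mean()
    k_eff = min(k, n)
    mse = np.zeros(alphas.size)
    for r in range(repeats):
        kf = KFold(n_splits=k_eff, shuffle=True, random_state=seed + r)
        for tr, te in kf.split(X):
            mu = X[tr].mean(axis=0)
            Xtr = X[tr] - mu
            ym = yc[tr].mean()
            W = _ridge_solve(Xtr, yc[tr] - ym, alphas)
            pred = (X[te] - mu) @ W + ym
            mse += np.mean((pred - yc[te][:, None]) ** 2, axis=0)
    mse /= repeats * k_eff
    best = int(np.argmin(mse))
    alpha = float(alphas[best])
    mu = X.mean(axis=0)
    w = _ridge_solve(X - mu, yc, np.array([alpha]))[:, 0]
    intercept = float(y.mean() - mu @ w)
    return alpha, dict(zip(snp_ids, w)), intercept


# -- per-gene orchestration ----------------------------------------------

def build_expression_model(gene_id: str, y: np.ndarray, X: np.ndarray, snp_ids,
                           positions=None, profile: BuilderProfile | None = None,
                           seed: int = 0) -> ExpressionModel:
    """Run LASSO -> forward filter -> ridge for one gene.

    An empty LASSO selection yields an intercept-only model (``n_snps ==
    0``) flagged ``intercept_only``; such models are not carried
    downstream.
    """
    prof = profile or BuilderProfile.default()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    snp_ids = list(snp_ids)
    lam, sel_ids, sel_idx = lasso_select(
        y, X, snp_ids, n_lambda=prof.n_lambda, k=prof.k,
        repeats=prof.lasso_repeats, seed=seed)
    if len(sel_ids) == 0:
        return ExpressionModel(gene_id, [], {}, intercept=float(y.mean()),
                               lambda_lasso=lam, flags=["intercept_only"])
    pos = None if positions is None else np.asarray(positions)[sel_idx]
    kept, r2_full, r2_filt, flags = forward_filter(
        y, X[:, sel_idx], sel_ids, positions=pos,
        threshold=prof.r2_threshold, seed=seed + 1)
    kept_idx = [snp_ids.index(s) for s in kept]
    alpha, weights, intercept = ridge_smooth(
        y, X[:, kept_idx], kept, k=prof.k, repeats=prof.ridge_repeats,
        seed=seed + 2)
    return ExpressionModel(gene_id, kept, weights, intercept=intercept,
                           lambda_lasso=lam, ridge_alpha=alpha,
                           r2_full=r2_full, r2_filtered=r2_filt, flags=flags)


def build_models(residual_expr: pd.DataFrame, panel: GenotypePanel,
                 windows: list[CisWindow], profile: BuilderProfile | None = None,
                 seed: int = 0) -> list[ExpressionModel]:
    """Build models for every gene with at least one cis SNP."""
    models = []
    win_by_gene = {w.gene_id: w for w in windows}
    for gi, gene_id in enumerate(residual_expr.index):
        w = win_by_gene.get(gene_id)
        if w is None:
            continue
        snps = panel.snps_in_window(w.chrom, w.start, w.end)
        if not snps:
            continue
        idx = panel.indices(snps)
        X = panel.dosages[:, idx].astype(float)
        y = residual_expr.loc[gene_id].to_numpy(dtype=float)
        m = build_expression_model(gene_id, y, X, snps,
                                   positions=panel.positions[idx],
                                   profile=profile, seed=seed + 1000 * gi)
        models.append(m)
    return models


# -- pre-validated model fit ----------------------------------------------

def prevalidated_prediction(y: np.ndarray, X: np.ndarray, ridge_alpha: float,
                            k: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold ridge predictions at the model's chosen penalty."""
    n = X.shape[0]
    k_eff = min(k, n)
    if k_eff < k:
        logger.info("reducing fold count to %d (n=%d)", k_eff, n)
    yhat = np.empty(n)
    kf = KFold(n_splits=k_eff, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        mu = X[tr].mean(axis=0)
        ym = y[tr].mean()
        w = _ridge_solve(X[tr] - mu, y[tr] - ym, np.array([ridge_alpha]))[:, 0]
        yhat[te] = (X[te] - mu) @ w + ym
    return yhat


def model_fit_qvalues(models: list[ExpressionModel], expr: pd.DataFrame,
                      panel: GenotypePanel, k: int = 10, seed: int = 0,
                      fdr: float = 0.01):
    """Pre-validated fit p-values and study-wide BH q-values.

    Each gene's observed expression is regressed on its out-of-fold ridge
    prediction; the slope t-test p-value is the model-fit p.  BH is
    applied across all supplied models (pool models from several datasets
    before calling for a study-wide correction).  Returns the models that
    pass ``fit_q < fdr``; every model has ``fit_p``/``fit_q`` set in place.
    """
    testable = [m for m in models if m.n_snps > 0]
    for m in testable:
        y = expr.loc[m.gene_id].to_numpy(dtype=float)
        X = panel.dosage(m.snp_ids)
        yhat = prevalidated_prediction(y, X, m.ridge_alpha, k=k, seed=seed)
        if yhat.std() == 0 or y.std() == 0:
            m.fit_p = 1.0
            continue
        r = np.corrcoef(y, yhat)[0, 1]
        n = y.size
        t = r * np.sqrt(max(n - 2, 1)) / np.sqrt(max(1 - r**2, 1e-300))
        # one-sided: only a positive predictive correlation is evidence of
        # fit, and under the null the pooled out-of-fold predictions are
        # biased toward *negative* correlation (the held-out fold's values
        # are anti-correlated with the training-fold mean), which a
        # two-sided test would mistake for signal
        m.fit_p = float(stats.t.sf(t, df=n - 2))
    if testable:
        qs = bh_qvalues(np.array([m.fit_p for m in testable]))
        for m, q in zip(testable, qs):
            m.fit_q = float(q)
    return [m for m in testable if m.fit_q < fdr]


def cv_r2(y: np.ndarray, X: np.ndarray, ridge_alpha: float = 0.0, k: int = 10,
          seed: int = 0) -> float:
    """Out-of-fold R^2 of a (ridge or OLS) fit; the model-comparison metric."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    yhat = prevalidated_prediction(y, X, ridge_alpha, k=k, seed=seed)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0


def models_table(models: list[ExpressionModel], panel: GenotypePanel) -> pd.DataFrame:
    """One row per gene-SNP weight, with alleles from the panel."""
    rows = []
    for m in models:
        for s in m.snp_ids:
            j = panel._index[s]
            rows.append({
                "gene_id": m.gene_id, "snp_id": s,
                "weight": m.snp_weights[s],
                "ref_allele": panel.a2[j], "eff_allele": panel.a1[j],
                "lambda": m.lambda_lasso, "ridge_alpha": m.ridge_alpha,
                "r2_full": m.r2_full, "r2_filtered": m.r2_filtered,
                "fit_p": m.fit_p, "fit_q": m.fit_q,
            })
    return pd.DataFrame(rows)
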