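"""Approximate conditional analysis of GWAS summary statistics.

Given marginal per-SNP effects and a reference LD panel, each remaining
SNP j is re-estimated jointly with the conditioning set S by solving the
joint least-squares normal equations in summary form: with Gamma the
reference dosage covariance and c_j = beta_j * Gamma_jj the implied
SNP-phenotype covariances,

    b = Gamma_{S+j, S+j}^{-1} c_{S+j},
    SSE = (n - 1) * (var_y - c' b),
    se(b_j)^2 = SSE / (n - p - 1) * [Gamma^{-1}]_jj / (n - 1).

The phenotypic variance var_y is reconstructed exactly from each SNP's
marginal statistics, var_y = var_j * (beta_j^2 + (n - 2) * se_j^2), and
the median across SNPs is used.  When the reference panel is the GWAS
cohort itself this reproduces individual-level joint-OLS t-statistics to
machine precision; with an external panel it is the usual approximate
conditional (COJO-style) estimator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_builder import ExpressionModel
from .twas import LdReference, TwasResult, sigma_g

logger = logging.getLogger(__name__)


def implied_phenotype_variance(gwas: pd.DataFrame, ref: LdReference,
                               n_gwas: int) -> float:
    """Median across SNPs of the per-SNP reconstruction of var(y)."""
    snps = [s for s in gwas["SNP"] if s in ref.panel._index]
    var = ref.sigma(snps) ** 2
    gw = gwas.set_index("SNP").loc[snps]
    beta = gw["BETA"].to_numpy(dtype=float)
    se = gw["SE"].to_numpy(dtype=float)
    return float(np.median(var * (beta**2 + (n_gwas - 2) * se**2)))


@dataclass
class ConditionalGwas:
    """Conditioned summary statistics; conditioned SNPs are absent."""

    conditioned_on: list[str]
    table: pd.DataFrame  # SNP, BETA_C, SE_C, Z_C, flags


def condition_summary(gwas: pd.DataFrame, ref: LdReference, snps,
                      n_gwas: int, collinear_r2: float = 0.99) -> ConditionalGwas:
    """Condition the GWAS on a SNP set; re-estimate every remaining SNP.

    SNPs with reference r^2 > ``collinear_r2`` against the conditioning
    set get z_c = 0 and a ``collinear`` flag.  A singular conditioning
    covariance is ridge-regularized with 1e-6 * I (warned).
    """
    cond = [s for s in snps]
    gw = gwas.set_index("SNP")
    missing = [s for s in cond if s not in gw.index]
    if missing:
        raise KeyError(f"conditioning SNPs lack GWAS records: {missing}")
    targets = [s for s in gw.index if s not in set(cond) and s in ref.panel._index]
    if not cond:
        tab = pd.DataFrame({
            "SNP": targets,
            "BETA_C": gw.loc[targets, "BETA"].to_numpy(dtype=float),
            "SE_C": gw.loc[targets, "SE"].to_numpy(dtype=float),
            "Z_C": (gw.loc[targets, "BETA"] / gw.loc[targets, "SE"]).to_numpy(dtype=float),
            "flags": "",
        })
        return ConditionalGwas([], tab)

    var_y = implied_phenotype_variance(gwas, ref, n_gwas)
    all_ids = cond + targets
    gamma = ref.cov(all_ids)
    s_ix = np.arange(len(cond))
    g_ss = gamma[np.ix_(s_ix, s_ix)]
    try:
        np.linalg.cholesky(g_ss)
    except np.linalg.LinAlgError:
        logger.warning("singular conditioning covariance; adding 1e-6 ridge")
        g_ss = g_ss + 1e-6 * np.eye(len(cond))
    beta_all = gw.loc[all_ids, "BETA"].to_numpy(dtype=float)
    c_all = beta_all * np.diag(gamma)
    c_s = c_all[s_ix]
    g_ss_inv = np.linalg.inv(g_ss)

    n = n_gwas
    p_joint = len(cond) + 1
    rows = []
    for t_i, snp in enumerate(targets):
        j = len(cond) + t_i
        g_jj = gamma[j, j]
        g_js = gamma[j, s_ix]
        r2_js = float(g_js @ g_ss_inv @ g_js / g_jj) if g_jj > 0 else 1.0
        if g_jj <= 0 or r2_js > collinear_r2:
            rows.append((snp, 0.0, np.nan, 0.0, "collinear"))
            continue
        # joint solve on {S, j} via block inversion
        d_j = g_jj - g_js @ g_ss_inv @ g_js  # conditional dosage variance
        b_j = (c_all[j] - g_js @ g_ss_inv @ c_s) / d_j
        b_s = g_ss_inv @ (c_s - g_js * b_j)
        explained = float(b_j * c_all[j] + b_s @ c_s)
        sse = (n - 1) * max(var_y - explained, 0.0)
        sigma2 = sse / max(n - p_joint - 1, 1)
        se_j = np.sqrt(sigma2 / ((n - 1) * d_j))
        z_j = b_j / se_j if se_j > 0 else 0.0
        rows.append((snp, b_j, se_j, z_j, ""))
    tab = pd.DataFrame(rows, columns=["SNP", "BETA_C", "SE_C", "Z_C", "flags"])
    return ConditionalGwas(cond, tab)


def conditional_twas(models: list[ExpressionModel], cond: ConditionalGwas,
                     ref: LdReference, alpha: float,
                     phenotype_id: str = "phenotype",
                     dataset_id: str = "dataset") -> pd.DataFrame:
    """Re-run the TWAS scan on conditioned Z scores.

    The conditioned SNPs are removed from every model and sigma_g is
    recomputed on the reduced SNP set; significance is judged at the
    caller-supplied threshold ``alpha`` (a Bonferroni-style p cutoff).
    Models whose SNPs are all conditioned away are reported as fully
    explained by the conditioning set.
    """
    ct = cond.table.set_index("SNP")
    dropped = set(cond.conditioned_on)
    rows = []
    for m in models:
        kept = [s for s in m.snp_ids if s not in dropped]
        if not kept:
            rows.append({
                "gene_id": m.gene_id, "phenotype_id": phenotype_id,
                "dataset_id": dataset_id, "z_conditional": np.nan,
                "p_conditional": np.nan, "significant": False,
                "status": "fully_explained",
            })
            continue
        present = [s for s in kept if s in ct.index]
        if not present:
            continue
        reduced = ExpressionModel(
            m.gene_id, present, {s: m.snp_weights[s] for s in present})
        sg = sigma_g(reduced, ref)
        if sg == 0:
            continue
        sigmas = ref.sigma(present)
        zc = ct.loc[present, "Z_C"].to_numpy(dtype=float)
        w = reduced.weights_array()
        z = float(np.sum(w * sigmas / sg * zc))
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({
            "gene_id": m.gene_id, "phenotype_id": phenotype_id,
            "dataset_id": dataset_id, "z_conditional": z, "p_conditional": p,
            "significant": p <= alpha, "status": "tested",
        })
    return pd.DataFrame(rows)


def condition_and_retest(model: ExpressionModel, result: TwasResult,
                         gwas: pd.DataFrame, ref: LdReference, n_gwas: int,
                         alpha: float, top_snp: str) -> pd.DataFrame:
    """Convenience one-gene path: condition on ``top_snp`` and re-test."""
    cond = condition_summary(gwas, ref, [top_snp], n_gwas)
    return conditional_twas([model], cond, ref, alpha,
                            phenotype_id=result.phenotype_id,
                            dataset_id=result.dataset_id)
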