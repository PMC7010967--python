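"""Colocalization posterior probabilities by causal-configuration enumeration.

For each trait the observed per-SNP Z vector over a locus is modeled as
multivariate normal with covariance equal to the LD matrix and mean
``ld @ lambda_c``, where ``lambda_c`` places a non-centrality of ``ncp``
(signed by the observed Z) at each causal SNP of configuration c and 0
elsewhere.  Configurations up to ``max_causal`` causal SNPs (including
the empty, null configuration) carry independent-Bernoulli priors; the
per-SNP causal posterior is the summed posterior of configurations
containing that SNP, and the colocalization posterior probability is

    CLPP_i = P(SNP i causal | trait 1) * P(SNP i causal | trait 2).

Because the mean is ``Sigma @ lambda``, the log Bayes factor of a
configuration against the null reduces to ``lambda' z - lambda' Sigma
lambda / 2`` and no per-configuration solve is needed.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_NCP = 5.2
DEFAULT_PRIOR = 0.01
DEFAULT_MAX_CAUSAL = 2
LOCUS_CAP = 50


def _ensure_psd(ld: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    evals = np.linalg.eigvalsh(ld)
    if evals[0] >= tol:
        return ld
    logger.warning("LD matrix not positive definite (min eig %.2e); repairing", evals[0])
    w, v = np.linalg.eigh((ld + ld.T) / 2.0)
    w = np.clip(w, tol, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _configurations(m: int, max_causal: int):
    for k in range(0, max_causal + 1):
        yield from itertools.combinations(range(m), k)


def snp_causal_posteriors(z: np.ndarray, ld: np.ndarray,
                          max_causal: int = DEFAULT_MAX_CAUSAL,
                          prior: float = DEFAULT_PRIOR,
                          ncp: float = DEFAULT_NCP) -> np.ndarray:
    """Per-SNP causal posterior for one trait by exhaustive enumeration."""
    z = np.asarray(z, dtype=float)
    m = z.size
    ld = _ensure_psd(np.asarray(ld, dtype=float).reshape(m, m))
    signs = np.where(z >= 0, 1.0, -1.0)
    log_prior_ratio = np.log(prior) - np.log(1.0 - prior)

    configs = list(_configurations(m, max_causal))
    log_post = np.empty(len(configs))
    for ci, c in enumerate(configs):
        if not c:
            log_post[ci] = 0.0  # null reference point
            continue
        idx = np.array(c)
        lam = ncp * signs[idx]
        log_bf = lam @ z[idx] - 0.5 * lam @ ld[np.ix_(idx, idx)] @ lam
        log_post[ci] = log_bf + len(c) * log_prior_ratio
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    per_snp = np.zeros(m)
    for ci, c in enumerate(configs):
        for i in c:
            per_snp[i] += post[ci]
    return per_snp


def clpp(z_eqtl: np.ndarray, z_gwas: np.ndarray, ld: np.ndarray,
         max_causal: int = DEFAULT_MAX_CAUSAL, prior: float = DEFAULT_PRIOR,
         ncp: float = DEFAULT_NCP) -> np.ndarray:
    """Per-SNP colocalization posterior probabilities over a locus."""
    z_eqtl = np.asarray(z_eqtl, dtype=float)
    z_gwas = np.asarray(z_gwas, dtype=float)
    if z_eqtl.size != z_gwas.size:
        raise ValueError("trait Z vectors must share the SNP ordering")
    p1 = snp_causal_posteriors(z_eqtl, ld, max_causal, prior, ncp)
    p2 = snp_causal_posteriors(z_gwas, ld, max_causal, prior, ncp)
    return p1 * p2


def eligibility(model_snps, eqtl_records: pd.DataFrame, gwas: pd.DataFrame,
                eqtl_fdr: float = 0.01, gwas_p: float = 5e-8):
    """Colocalization eligibility of a gene-phenotype association.

    Eligible iff at least one model SNP is a significant cis-eQTL
    (q < ``eqtl_fdr``) and reaches genome-wide significance in the GWAS
    (p <= ``gwas_p``).  Returns ``(eligible, qualifying_snp_set)``.
    """
    model_snps = list(model_snps)
    if not model_snps:
        return False, set()
    eq = eqtl_records.set_index("snp_id") if "snp_id" in eqtl_records.columns else eqtl_records
    gw = gwas.set_index("SNP") if gwas.index.name != "SNP" else gwas
    qualifying = set()
    for s in model_snps:
        if s not in eq.index or s not in gw.index:
            continue
        q = eq.loc[s, "q"]
        q = float(np.min(q)) if np.ndim(q) else float(q)
        if q < eqtl_fdr and float(gw.loc[s, "P"]) <= gwas_p:
            qualifying.add(s)
    return bool(qualifying), qualifying


@dataclass
class ColocResult:
    gene_id: str
    phenotype_id: str
    dataset_id: str
    eligible: bool
    snp_clpp: dict[str, float] = field(default_factory=dict)
    model_snp_clpp: dict[str, float] = field(default_factory=dict)
    max_clpp: float = np.nan
    colocalized: bool = False


def colocalize_gene(model_snps, gene_id: str, eqtl_records: pd.DataFrame,
                    gwas: pd.DataFrame, ref, phenotype_id: str = "phenotype",
                    dataset_id: str = "dataset", eqtl_fdr: float = 0.01,
                    gwas_p: float = 5e-8, threshold: float = 0.01,
                    max_causal: int = DEFAULT_MAX_CAUSAL,
                    prior: float = DEFAULT_PRIOR, ncp: float = DEFAULT_NCP,
                    locus_cap: int = LOCUS_CAP) -> ColocResult:
    """CLPP over the locus of one gene-phenotype association.

    The locus is the intersection of the gene's tested cis SNPs and the
    GWAS coverage, capped at ``locus_cap`` SNPs (the model SNPs plus the
    highest-|Z| GWAS SNPs).  The colocalized call uses the qualifying
    model SNPs only: colocalized iff any has CLPP > ``threshold``.
    """
    eq_gene = eqtl_records[eqtl_records["gene_id"] == gene_id]
    eligible, qualifying = eligibility(model_snps, eq_gene, gwas, eqtl_fdr, gwas_p)
    res = ColocResult(gene_id, phenotype_id, dataset_id, eligible)
    if not eligible:
        return res
    gw = gwas.set_index("SNP")
    locus = [s for s in eq_gene["snp_id"] if s in gw.index]
    if len(locus) > locus_cap:
        zabs = (gw.loc[locus, "BETA"] / gw.loc[locus, "SE"]).abs()
        keep = set(model_snps) & set(locus)
        for s in zabs.sort_values(ascending=False).index:
            if len(keep) >= locus_cap:
                break
            keep.add(s)
        locus = [s for s in locus if s in keep]
    eq_z = (eq_gene.set_index("snp_id").loc[locus, "beta"]
            / eq_gene.set_index("snp_id").loc[locus, "se"]).to_numpy(dtype=float)
    gw_z = (gw.loc[locus, "BETA"] / gw.loc[locus, "SE"]).to_numpy(dtype=float)
    ld = ref.ld(locus)
    vals = clpp(eq_z, gw_z, ld, max_causal=max_causal, prior=prior, ncp=ncp)
    res.snp_clpp = dict(zip(locus, vals))
    res.model_snp_clpp = {s: res.snp_clpp[s] for s in qualifying if s in res.snp_clpp}
    if res.model_snp_clpp:
        res.max_clpp = max(res.model_snp_clpp.values())
        res.colocalized = res.max_clpp > threshold
    return res


def call_colocalization(results: list[ColocResult],
                        threshold: float = 0.01) -> pd.DataFrame:
    """Aggregate per-dataset results into gene-phenotype calls.

    A pair is ``colocalized`` if any model SNP in any dataset exceeds the
    CLPP threshold, ``not_colocalized`` if tested everywhere without an
    exceedance, and ``not_tested`` if ineligible in every dataset.
    """
    rows: dict[tuple[str, str], dict] = {}
    for r in results:
        key = (r.gene_id, r.phenotype_id)
        entry = rows.setdefault(key, {"eligible": False, "max_clpp": np.nan,
                                      "colocalized": False})
        if r.eligible:
            entry["eligible"] = True
            if np.isfinite(r.max_clpp):
                prev = entry["max_clpp"]
                entry["max_clpp"] = r.max_clpp if np.isnan(prev) else max(prev, r.max_clpp)
            if np.isfinite(r.max_clpp) and r.max_clpp > threshold:
                entry["colocalized"] = True
    out = []
    for (g, ph), e in rows.items():
        call = ("colocalized" if e["colocalized"]
                else "not_colocalized" if e["eligible"] else "not_tested")
        out.append({"gene_id": g, "phenotype_id": ph, "eligible": e["eligible"],
                    "max_clpp": e["max_clpp"], "call": call})
    return pd.DataFrame(out)
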