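"""Summary-statistic TWAS with per-SNP decomposition.

The gene-level association statistic is the S-PrediXcan form

    Z_g = sum_{l in model_g} w_lg * (sigma_l / sigma_g) * beta_l / se(beta_l)

where w_lg are the expression-model weights, sigma_l is the reference
standard deviation of SNP l's dosage, and sigma_g = sqrt(w' Gamma w) is
the reference standard deviation of the model-predicted expression
(Gamma the dosage covariance).  Each summand is stored, so the Z score
decomposes exactly into per-SNP contributions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .model_builder import ExpressionModel
from .synthetic import GenotypePanel

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class LdReference:
    """Per-SNP dosage SDs and pairwise covariance from a reference panel."""

    def __init__(self, panel: GenotypePanel):
        self.panel = panel
        self.n = panel.n_samples

    def sigma(self, snp_ids) -> np.ndarray:
        X = self.panel.dosage(snp_ids)
        return X.std(axis=0, ddof=1)

    def cov(self, snp_ids) -> np.ndarray:
        return self.panel.cov(snp_ids)

    def ld(self, snp_ids) -> np.ndarray:
        return self.panel.ld(snp_ids)

    def positions(self, snp_ids) -> np.ndarray:
        return self.panel.positions[self.panel.indices(snp_ids)]


def harmonize(gwas: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Align GWAS effect alleles to the panel's counted alleles.

    Matching alleles pass through; swapped alleles flip the sign of BETA
    and Z; strand-ambiguous (A/T, C/G) and otherwise unmatched SNPs are
    dropped (logged).
    """
    idx = {s: i for i, s in enumerate(panel.snp_ids)}
    out = gwas.copy()
    keep = np.ones(len(out), dtype=bool)
    flip = np.zeros(len(out), dtype=bool)
    n_ambig = n_unmatched = n_absent = 0
    for r, row in enumerate(out.itertuples()):
        j = idx.get(row.SNP)
        if j is None:
            keep[r] = False
            n_absent += 1
            continue
        a1, a2 = str(row.A1), str(row.A2)
        if (a1, a2) in AMBIGUOUS_PAIRS:
            keep[r] = False
            n_ambig += 1
            continue
        if a1 == panel.a1[j] and a2 == panel.a2[j]:
            continue
        if a1 == panel.a2[j] and a2 == panel.a1[j]:
            flip[r] = True
        else:
            keep[r] = False
            n_unmatched += 1
    if n_ambig or n_unmatched or n_absent:
        logger.info("harmonize dropped %d ambiguous, %d allele-mismatched, "
                    "%d panel-absent SNPs", n_ambig, n_unmatched, n_absent)
    out.loc[flip, "BETA"] *= -1.0
    if "Z" in out.columns:
        out.loc[flip, "Z"] *= -1.0
    a1 = out.loc[flip, "A1"].copy()
    out.loc[flip, "A1"] = out.loc[flip, "A2"]
    out.loc[flip, "A2"] = a1
    return out[keep].reset_index(drop=True)


def sigma_g(model: ExpressionModel, ref: LdReference) -> float:
    """Reference-panel SD of the model-predicted expression: sqrt(w' Gamma w)."""
    w = model.weights_array()
    gamma = ref.cov(model.snp_ids)
    val = float(np.sqrt(max(w @ gamma @ w, 0.0)))
    return val


@dataclass
class TwasResult:
    gene_id: str
    phenotype_id: str
    dataset_id: str
    z: float
    p: float
    sigma_g: float
    contributions: dict[str, float]
    coverage: float
    n_model_snps: int
    q: float = np.nan
    flags: list[str] = field(default_factory=list)


def spredixcan_z(model: ExpressionModel, gwas: pd.DataFrame, ref: LdReference,
                 phenotype_id: str = "phenotype", dataset_id: str = "dataset",
                 ) -> TwasResult | None:
    """Gene-phenotype Z from harmonized GWAS summary statistics.

    Model SNPs missing from the GWAS are dropped from the sum (the
    retained fraction is reported as ``coverage``); zero coverage or a
    degenerate sigma_g yields no result.
    """
    gw = gwas.set_index("SNP") if gwas.index.name != "SNP" else gwas
    present = [s for s in model.snp_ids if s in gw.index]
    if not present:
        logger.warning("%s: no model SNP present in GWAS", model.gene_id)
        return None
    coverage = len(present) / model.n_snps
    sg = sigma_g(model, ref)
    if sg == 0:
        logger.warning("%s: degenerate predicted-expression variance", model.gene_id)
        return None
    sigmas = ref.sigma(present)
    zl = (gw.loc[present, "BETA"] / gw.loc[present, "SE"]).to_numpy(dtype=float)
    w = np.array([model.snp_weights[s] for s in present])
    terms = w * sigmas / sg * zl
    z = float(terms.sum())
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TwasResult(model.gene_id, phenotype_id, dataset_id, z, p, sg,
                      dict(zip(present, terms)), coverage, model.n_snps)


def top_contributing_snp(result: TwasResult, ref: LdReference) -> str:
    """Model SNP with the largest |contribution| among those sharing Z's sign.

    Ties are broken by genomic position.  Raises if no contribution has
    the same sign as the overall Z (flagged for manual review upstream).
    """
    sign = np.sign(result.z)
    same = {s: c for s, c in result.contributions.items() if np.sign(c) == sign}
    if not same:
        raise ValueError(f"{result.gene_id}: no contribution shares the Z sign")
    ids = list(same)
    mags = np.array([abs(same[s]) for s in ids])
    pos = ref.positions(ids)
    order = np.lexsort((pos, -mags))
    return ids[order[0]]


def association_scan(models: list[ExpressionModel],
                     gwas_by_phenotype: dict[str, pd.DataFrame],
                     ref: LdReference, fdr: float = 0.01,
                     dataset_id: str = "dataset"):
    """All gene x phenotype tests with study-wide BH correction.

    Returns ``(results, table)``; ``table`` has one row per test with q
    and a ``significant`` flag at ``q < fdr``.
    """
    results: list[TwasResult] = []
    for pheno_id, gwas in gwas_by_phenotype.items():
        gw = gwas.set_index("SNP")
        for m in models:
            if m.n_snps == 0:
                continue
            r = spredixcan_z(m, gw, ref, phenotype_id=pheno_id,
                             dataset_id=dataset_id)
            if r is not None:
                results.append(r)
    if results:
        qs = bh_qvalues(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    rows = []
    for r in results:
        try:
            top = top_contributing_snp(r, ref)
        except ValueError:
            top = ""
            r.flags.append("no_same_sign_snp")
        rows.append({
            "gene_id": r.gene_id, "phenotype_id": r.phenotype_id,
            "dataset_id": r.dataset_id, "z": r.z, "p": r.p, "q": r.q,
            "n_model_snps": r.n_model_snps, "coverage": r.coverage,
            "top_contributing_snp": top, "significant": r.q < fdr,
        })
    columns = ["gene_id", "phenotype_id", "dataset_id", "z", "p", "q",
               "n_model_snps", "coverage", "top_contributing_snp", "significant"]
    table = pd.DataFrame(rows, columns=columns)
    return results, table
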