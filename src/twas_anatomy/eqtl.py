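"""Single-variant cis-eQTL scan and per-gene top-eQTL selection.

Each SNP within 1 Mb of a gene's transcription start/end is tested by
simple linear regression of residualized expression on dosage.  q-values
are Benjamini-Hochberg across every gene-SNP test in the dataset (a
nominal-p FDR in place of permutation-based schemes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, marginal_ols
from .synthetic import GenotypePanel

logger = logging.getLogger(__name__)

CIS_FLANK = 1_000_000


@dataclass(frozen=True)
class CisWindow:
    """Closed 1-based cis window: [TSS - flank, TES + flank], clamped at 1."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_gene(cls, gene_id: str, chrom: str, tss: int, tes: int,
                  flank: int = CIS_FLANK) -> "CisWindow":
        return cls(gene_id, chrom, max(1, tss - flank), tes + flank)


def cis_windows(annotations: pd.DataFrame, flank: int = CIS_FLANK) -> list[CisWindow]:
    return [
        CisWindow.from_gene(r.gene_id, str(r.chrom), int(r.tss), int(r.tes), flank)
        for r in annotations.itertuples()
    ]


def cis_scan(residual_expr: pd.DataFrame, panel: GenotypePanel,
             windows: list[CisWindow]) -> pd.DataFrame:
    """Per-gene, per-cis-SNP simple regression scan.

    Returns one row per gene-SNP test with beta (expression SD per
    counted allele when expression is standardized), se, p and BH q
    computed across all tests.  Zero-variance dosages are skipped.
    """
    if residual_expr.shape[1] != panel.n_samples:
        raise ValueError("expression samples do not match genotype panel")
    frames = []
    for w in windows:
        if w.gene_id not in residual_expr.index:
            continue
        snps = panel.snps_in_window(w.chrom, w.start, w.end)
        if not snps:
            continue
        idx = panel.indices(snps)
        X = panel.dosages[:, idx].astype(float)
        y = residual_expr.loc[w.gene_id].to_numpy(dtype=float)
        beta, se, _t, p, valid = marginal_ols(y, X)
        if (~valid).any():
            logger.info("%s: skipped %d zero-variance SNPs", w.gene_id, int((~valid).sum()))
        frames.append(pd.DataFrame({
            "gene_id": w.gene_id,
            "snp_id": np.asarray(snps, dtype=object)[valid],
            "chrom": panel.chroms[idx][valid],
            "bp": panel.positions[idx][valid],
            "beta": beta[valid], "se": se[valid], "p": p[valid],
        }))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "snp_id", "chrom", "bp",
                                     "beta", "se", "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def top_eqtl(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene record with the lowest p; ties broken by position then snp_id."""
    if records.empty:
        return records.copy()
    ordered = records.sort_values(["gene_id", "p", "bp", "snp_id"],
                                  kind="mergesort")
    return ordered.groupby("gene_id", as_index=False).head(1).reset_index(drop=True)
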