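"""Synthetic genotypes, expression, phenotypes and GWAS summary statistics.

The generator emulates the inputs of a multi-tissue TWAS of molecular
phenotypes: a diploid genotype panel with block-wise linkage
disequilibrium (LD), raw expression counts whose cis-genetic component has
a configurable architecture (number of causal eQTLs, heritability), and an
independent GWAS cohort from the same LD model whose phenotype's causal
variants can be shared with, in LD with, distinct from, or mediated by a
gene's genetically regulated expression.

LD is induced by an order-1 autoregressive latent Gaussian per haplotype,
thresholded at each SNP's minor-allele-frequency quantile; two independent
haplotypes are summed into a dosage in {0, 1, 2}.  Blocks are mutually
independent.  All positions are 1-based; cis windows are closed intervals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import marginal_ols

logger = logging.getLogger(__name__)

# non-strand-ambiguous allele pairs cycled across SNPs (counted, other)
_ALLELE_CYCLE = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


class ConfigError(ValueError):
    """Raised for degenerate scenario configurations."""


@dataclass
class LdBlockSpec:
    """One LD block: ``n_snps`` SNPs with adjacent latent correlation ``rho``."""

    n_snps: int
    rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    start_bp: int = 1
    spacing_bp: int = 2000
    chrom: str = "1"

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("LD block must contain at least one SNP")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if lo < 0.05 or hi > 0.5 or lo > hi:
            raise ConfigError(f"maf_range must be within [0.05, 0.5], got {self.maf_range}")
        if self.start_bp < 1 or self.spacing_bp < 1:
            raise ConfigError("positions are 1-based; start_bp and spacing_bp must be >= 1")


@dataclass
class GeneArchitecture:
    """Cis architecture of one gene: causal SNPs with effects in expression-SD units."""

    gene_id: str
    tss: int
    tes: int
    causal_snps: list[tuple[str, float]] = field(default_factory=list)
    h2: float = 0.0
    chrom: str = "1"

    def validate(self) -> None:
        if self.tes < self.tss:
            raise ConfigError(f"{self.gene_id}: tes < tss")
        if not (0.0 <= self.h2 < 1.0):
            raise ConfigError(f"{self.gene_id}: h2 must be in [0, 1)")


#: phenotype causal-variant relationships to the eQTL architecture
PHENOTYPE_MODES = ("shared_with_eqtl", "ld_tagged", "distinct", "mediated_by_gene")


@dataclass
class PhenotypeArchitecture:
    """Phenotype causal structure; effects are in phenotype-SD units.

    ``mode`` records how the causal variants relate to the eQTL
    architecture.  ``mediated_by_gene`` ignores ``causal_snps`` and drives
    the phenotype with the genetic expression value of ``gene_id`` scaled
    by ``gene_effect``.
    """

    phenotype_id: str
    causal_snps: list[tuple[str, float]] = field(default_factory=list)
    mode: str = "distinct"
    gene_id: str | None = None
    gene_effect: float = 0.0

    def validate(self) -> None:
        if self.mode not in PHENOTYPE_MODES:
            raise ConfigError(f"unknown phenotype mode {self.mode!r}")
        if self.mode == "mediated_by_gene" and not self.gene_id:
            raise ConfigError(f"{self.phenotype_id}: mediated_by_gene requires gene_id")


@dataclass
class ScenarioConfig:
    n_samples: int
    n_gwas_samples: int
    blocks: list[LdBlockSpec]
    genes: list[GeneArchitecture] = field(default_factory=list)
    phenotypes: list[PhenotypeArchitecture] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 50:
            raise ConfigError("n_samples must be >= 50")
        if not self.blocks:
            raise ConfigError("at least one LD block is required")
        for b in self.blocks:
            b.validate()
        for g in self.genes:
            g.validate()
        for p in self.phenotypes:
            p.validate()


class GenotypePanel:
    """Samples x SNPs dosage matrix with positions, alleles and LD on demand.

    ``a1`` is the counted (dosage/effect) allele, ``a2`` the other allele.
    The panel keeps the per-SNP target MAF and block membership so that an
    independent cohort can be drawn from the same LD model.
    """

    def __init__(self, dosages, snp_ids, chroms, positions, a1, a2,
                 target_maf, block_index, block_specs):
        self.dosages = np.asarray(dosages)
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.chroms = np.asarray(chroms, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.a1 = np.asarray(a1, dtype=object)
        self.a2 = np.asarray(a2, dtype=object)
        self.target_maf = np.asarray(target_maf, dtype=float)
        self.block_index = np.asarray(block_index, dtype=np.int64)
        self.block_specs = list(block_specs)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def indices(self, snp_ids) -> np.ndarray:
        return np.array([self._index[s] for s in snp_ids], dtype=np.int64)

    def dosage(self, snp_ids) -> np.ndarray:
        return self.dosages[:, self.indices(snp_ids)].astype(float)

    def standardized_dosage(self, snp_ids) -> np.ndarray:
        X = self.dosage(snp_ids)
        return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    def ld(self, snp_ids) -> np.ndarray:
        """Pairwise dosage correlation matrix for the given SNPs."""
        X = self.dosage(snp_ids)
        return np.corrcoef(X, rowvar=False).reshape(len(snp_ids), len(snp_ids))

    def cov(self, snp_ids) -> np.ndarray:
        X = self.dosage(snp_ids)
        return np.atleast_2d(np.cov(X, rowvar=False))

    def snps_in_window(self, chrom: str, start: int, end: int) -> list[str]:
        mask = (self.chroms == chrom) & (self.positions >= start) & (self.positions <= end)
        return list(self.snp_ids[mask])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SNP": self.snp_ids, "CHR": self.chroms, "BP": self.positions,
            "A1": self.a1, "A2": self.a2, "MAF": self.maf,
        })


def _simulate_block_haplotypes(n_hap: int, spec: LdBlockSpec, maf: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """AR(1) latent Gaussian haplotypes thresholded at the MAF quantile."""
    m = spec.n_snps
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - spec.rho**2)
        for j in range(1, m):
            z[:, j] = spec.rho * z[:, j - 1] + scale * eps[:, j - 1]
    thresh = stats.norm.ppf(maf)
    return (z < thresh).astype(np.int8)


def simulate_genotypes(config: ScenarioConfig, n_samples: int | None = None,
                       seed: int | None = None) -> GenotypePanel:
    """Simulate a diploid dosage panel from the scenario's LD blocks.

    SNPs whose realized MAF falls below 0.05 after a bounded number of
    block re-draws are dropped (logged), so every retained SNP satisfies
    the MAF >= 0.05 filter of the study design.
    """
    config.validate()
    n = config.n_samples if n_samples is None else n_samples
    rng = np.random.default_rng(config.seed if seed is None else seed)

    dosage_cols, ids, chroms, pos, a1, a2, tmaf, bidx = [], [], [], [], [], [], [], []
    for bi, spec in enumerate(config.blocks):
        maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
        block = None
        for _attempt in range(10):
            hap = _simulate_block_haplotypes(2 * n, spec, maf, rng)
            dos = hap[:n] + hap[n:]
            freq = dos.mean(axis=0) / 2.0
            realized = np.minimum(freq, 1 - freq)
            if np.all(realized >= 0.05):
                block = dos
                keep = np.ones(spec.n_snps, dtype=bool)
                break
        if block is None:
            keep = realized >= 0.05
            block = dos
            logger.warning("block %d: dropping %d SNPs with realized MAF < 0.05",
                           bi, int((~keep).sum()))
        for j in range(spec.n_snps):
            if not keep[j]:
                continue
            p = spec.start_bp + j * spec.spacing_bp
            dosage_cols.append(block[:, j])
            ids.append(f"s{spec.chrom}_{p}")
            chroms.append(spec.chrom)
            pos.append(p)
            pair = _ALLELE_CYCLE[(bi + j) % len(_ALLELE_CYCLE)]
            a1.append(pair[0])
            a2.append(pair[1])
            tmaf.append(maf[j])
            bidx.append(bi)
    if not dosage_cols:
        raise ConfigError("no SNPs retained after MAF filtering")
    return GenotypePanel(np.column_stack(dosage_cols), ids, chroms, pos, a1, a2,
                         tmaf, bidx, config.blocks)


def resample_cohort(panel: GenotypePanel, n: int, seed: int) -> GenotypePanel:
    """Draw an independent cohort from the panel's LD model, keeping its SNP set.

    Realized MAF is not re-enforced in the cohort; monomorphic SNPs are
    handled downstream at regression time.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for bi, spec in enumerate(panel.block_specs):
        mask = panel.block_index == bi
        if not mask.any():
            continue
        # re-simulate the full block, then keep the retained columns
        full_maf = np.full(spec.n_snps, np.nan)
        kept_pos = (panel.positions[mask] - spec.start_bp) // spec.spacing_bp
        full_maf[kept_pos] = panel.target_maf[mask]
        # fill dropped positions with a mid-range MAF so AR chain length is preserved
        full_maf[np.isnan(full_maf)] = 0.25
        hap = _simulate_block_haplotypes(2 * n, spec, full_maf, rng)
        dos = hap[:n] + hap[n:]
        cols.append(dos[:, kept_pos])
    dosages = np.column_stack(cols)
    return GenotypePanel(dosages, panel.snp_ids, panel.chroms, panel.positions,
                         panel.a1, panel.a2, panel.target_maf, panel.block_index,
                         panel.block_specs)


# -- expression ----------------------------------------------------------

def genetic_expression(panel: GenotypePanel, gene: GeneArchitecture) -> np.ndarray:
    """Genetic component of a gene's expression: sum of effect * standardized dosage."""
    if not gene.causal_snps:
        return np.zeros(panel.n_samples)
    ids = [s for s, _ in gene.causal_snps]
    missing = [s for s in ids if s not in panel._index]
    if missing:
        raise KeyError(f"{gene.gene_id}: causal SNPs absent from panel: {missing}")
    betas = np.array([e for _, e in gene.causal_snps])
    return panel.standardized_dosage(ids) @ betas


def simulate_expression(panel: GenotypePanel, gene: GeneArchitecture,
                        seed: int) -> np.ndarray:
    """Latent (normalized-scale) expression with cis-h2 as configured.

    Gaussian noise is scaled so the genotype-explained variance fraction is
    ``gene.h2`` in expectation; ``h2 = 0`` yields pure noise.
    """
    gene.validate()
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    if gene.h2 == 0.0 or not gene.causal_snps:
        return rng.standard_normal(n)
    g = genetic_expression(panel, gene)
    var_g = g.var(ddof=1)
    noise_sd = np.sqrt(var_g * (1.0 - gene.h2) / gene.h2)
    return g + noise_sd * rng.standard_normal(n)


def simulate_counts(latent: pd.DataFrame, seed: int, dispersion: float = 0.1,
                    base_mean_range: tuple[float, float] = (2.0, 200.0),
                    depth_sd: float = 0.25, latent_scale: float = 1.0) -> pd.DataFrame:
    """Negative-binomial raw counts around exp(latent) with per-sample depths.

    Only needed so the expression filters have something to filter: gene
    base means are log-uniform over ``base_mean_range`` and a per-sample
    sequencing depth multiplier is lognormal with ``depth_sd``.  The
    latent normalized expression enters on the log link scaled by
    ``latent_scale``.
    """
    rng = np.random.default_rng(seed)
    G, n = latent.shape
    base = np.exp(rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), size=G))
    depth = np.exp(rng.normal(0.0, depth_sd, size=n))
    # center each gene's latent so h2 architecture, not scale, drives the mean
    lat = latent.to_numpy()
    lat = lat - lat.mean(axis=1, keepdims=True)
    mu = base[:, None] * np.exp(latent_scale * lat) * depth[None, :]
    if dispersion > 0:
        shape = 1.0 / dispersion
        mu = rng.gamma(shape, mu / shape)
    counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=latent.index, columns=latent.columns)


def simulate_expression_matrix(panel: GenotypePanel, genes: list[GeneArchitecture],
                               seed: int, dispersion: float = 0.1):
    """Latent and raw-count expression matrices (genes x samples) for a gene set."""
    sample_ids = [f"sample{i:04d}" for i in range(panel.n_samples)]
    lat = {}
    for i, gene in enumerate(genes):
        lat[gene.gene_id] = simulate_expression(panel, gene, seed=seed * 100003 + i)
    latent = pd.DataFrame.from_dict(lat, orient="index", columns=sample_ids)
    counts = simulate_counts(latent, seed=seed + 7)
    return latent, counts


def gene_annotation(genes: list[GeneArchitecture]) -> pd.DataFrame:
    """Gene annotation table (1-based closed coordinates)."""
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "tss": [g.tss for g in genes],
        "tes": [g.tes for g in genes],
    })


# -- phenotypes and GWAS summary statistics ------------------------------

def simulate_phenotype(cohort: GenotypePanel, pheno: PhenotypeArchitecture,
                       genes: list[GeneArchitecture], seed: int) -> np.ndarray:
    """Phenotype vector (unit variance in expectation) for a cohort."""
    pheno.validate()
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    if pheno.mode == "mediated_by_gene":
        gene = next((g for g in genes if g.gene_id == pheno.gene_id), None)
        if gene is None:
            raise ConfigError(f"{pheno.phenotype_id}: unknown mediating gene {pheno.gene_id}")
        g = genetic_expression(cohort, gene)
        sd = g.std(ddof=1)
        g = g / sd if sd > 0 else g
        eff = pheno.gene_effect
        var_g = eff**2
    elif pheno.causal_snps:
        ids = [s for s, _ in pheno.causal_snps]
        eff_vec = np.array([e for _, e in pheno.causal_snps])
        g = cohort.standardized_dosage(ids) @ eff_vec
        var_g = g.var(ddof=1)
        eff = 1.0
    else:
        g, var_g, eff = np.zeros(n), 0.0, 1.0
    if var_g >= 1.0:
        raise ConfigError(f"{pheno.phenotype_id}: genetic variance >= 1 phenotype SD^2")
    noise_sd = np.sqrt(1.0 - var_g)
    return eff * g + noise_sd * rng.standard_normal(n)


def gwas_summary_from_cohort(cohort: GenotypePanel, y: np.ndarray,
                             flip_fraction: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Per-SNP simple-regression summary statistics on an individual-level cohort.

    Monomorphic SNPs in the realized cohort are excluded (logged).  A
    ``flip_fraction`` of SNPs can be emitted with swapped alleles and
    negated betas to exercise harmonization downstream.
    """
    beta, se, _t, p, valid = marginal_ols(y, cohort.dosages.astype(float))
    n = cohort.n_samples
    dropped = int((~valid).sum())
    if dropped:
        logger.warning("excluding %d monomorphic SNPs from GWAS summary", dropped)
    df = pd.DataFrame({
        "SNP": cohort.snp_ids, "CHR": cohort.chroms, "BP": cohort.positions,
        "A1": cohort.a1, "A2": cohort.a2,
        "BETA": beta, "SE": se, "Z": beta / se, "P": p, "N": n,
    })[valid]
    if flip_fraction > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(df)) < flip_fraction
        df.loc[flip, ["A1", "A2"]] = df.loc[flip, ["A2", "A1"]].to_numpy()
        df.loc[flip, "BETA"] *= -1.0
        df.loc[flip, "Z"] *= -1.0
    return df.reset_index(drop=True)


def simulate_gwas_summary(panel: GenotypePanel, pheno: PhenotypeArchitecture,
                          genes: list[GeneArchitecture], n_gwas: int, seed: int,
                          flip_fraction: float = 0.0):
    """Draw an independent GWAS cohort and compute summary statistics.

    Returns ``(summary, cohort, y)``; the cohort and phenotype vector are
    exposed so individual-level oracles can be run against the summary
    path.
    """
    if n_gwas < 100:
        raise ConfigError("n_gwas must be >= 100")
    cohort = resample_cohort(panel, n_gwas, seed=seed)
    y = simulate_phenotype(cohort, pheno, genes, seed=seed + 1)
    summary = gwas_summary_from_cohort(cohort, y, flip_fraction=flip_fraction,
                                       seed=seed + 2)
    return summary, cohort, y


# -- writers -------------------------------------------------------------

def write_gwas_tsv(summary: pd.DataFrame, path) -> None:
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE"]
    extra = [c for c in summary.columns if c not in cols]
    summary[cols + extra].to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_annotation_bed(genes: list[GeneArchitecture], path) -> None:
    """4-column BED-like file; half-open on disk (start = tss - 1)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss - 1}\t{g.tes}\t{g.gene_id}\n")


def read_annotation_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id"],
                      dtype={"chrom": str})
    return pd.DataFrame({
        "gene_id": bed["gene_id"], "chrom": bed["chrom"],
        "tss": bed["start"] + 1, "tes": bed["end"],
    })


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages.T,
                      columns=[f"sample{i:04d}" for i in range(panel.n_samples)])
    meta = panel.table().drop(columns="MAF")
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypePanel:
    """Read a dosage table written by :func:`write_genotypes_tsv`.

    Block structure is not recoverable from disk, so the returned panel
    supports everything except drawing new cohorts from the LD model.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    meta_cols = ["SNP", "CHR", "BP", "A1", "A2"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(dtype=np.int8).T
    maf = np.minimum(dosages.mean(axis=0) / 2.0, 1 - dosages.mean(axis=0) / 2.0)
    return GenotypePanel(dosages, df["SNP"], df["CHR"], df["BP"], df["A1"],
                         df["A2"], maf, np.zeros(len(df)), [])


def write_genotypes_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with GT genotypes (counted allele written as ALT)."""
    samples = [f"sample{i:04d}" for i in range(panel.n_samples)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(panel.n_snps):
            gts = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{panel.chroms[j]}\t{panel.positions[j]}\t{panel.snp_ids[j]}\t"
                     f"{panel.a2[j]}\t{panel.a1[j]}\t.\tPASS\t.\tGT\t{gts}\n")
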