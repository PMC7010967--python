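"""Ready-made synthetic study designs.

These encode the causal configurations the analysis dissects: a single
gene with one or several independent cis-eQTLs driving a mediated
phenotype, and a multi-locus benchmark where each locus carries one
causal (mediating) gene plus pleiotropic "bystander" genes regulated by
the same variant.
"""
from __future__ import annotations

from .synthetic import (GeneArchitecture, LdBlockSpec, PhenotypeArchitecture,
                        ScenarioConfig)


def snp_id_at(chrom: str, start_bp: int, spacing_bp: int, j: int) -> str:
    return f"s{chrom}_{start_bp + j * spacing_bp}"


def single_gene_scenario(n_samples: int = 500, n_gwas: int = 5000,
                         n_snps: int = 30, rho: float = 0.6, h2: float = 0.5,
                         causal_idx: tuple[int, ...] = (14,),
                         gene_effect: float = 0.1, seed: int = 0,
                         maf_range: tuple[float, float] = (0.1, 0.5),
                         chrom: str = "1") -> ScenarioConfig:
    """One LD block, one gene, one phenotype mediated by the gene.

    ``causal_idx`` are SNP offsets within the block that act as
    independent cis-eQTLs of equal effect; ``gene_effect`` is the effect
    of standardized genetic expression on the phenotype (phenotype-SD
    units), so the expected GWAS-level signal scales with
    sqrt(n_gwas) * gene_effect.
    """
    start, spacing = 1_000_000, 2000
    block = LdBlockSpec(n_snps=n_snps, rho=rho, maf_range=maf_range,
                        start_bp=start, spacing_bp=spacing, chrom=chrom)
    causal = [(snp_id_at(chrom, start, spacing, j), 1.0) for j in causal_idx]
    mid = start + (n_snps // 2) * spacing
    gene = GeneArchitecture("gene1", tss=mid, tes=mid + 5000,
                            causal_snps=causal, h2=h2, chrom=chrom)
    pheno = PhenotypeArchitecture("pheno1", mode="mediated_by_gene",
                                  gene_id="gene1", gene_effect=gene_effect)
    return ScenarioConfig(n_samples=n_samples, n_gwas_samples=n_gwas,
                          blocks=[block], genes=[gene], phenotypes=[pheno],
                          seed=seed)


def bystander_benchmark_scenario(n_loci: int = 20, n_samples: int = 500,
                                 n_gwas: int = 3000, n_snps: int = 15,
                                 rho: float = 0.6, causal_h2: float = 0.4,
                                 bystander_h2: float = 0.35,
                                 gene_effect: float = 0.12,
                                 seed: int = 0) -> ScenarioConfig:
    """Multi-locus benchmark with pleiotropic shared-eQTL bystanders.

    Each locus sits on its own chromosome and carries one LD block, one
    causal gene that mediates the locus phenotype, and two bystander
    genes whose expression is driven by the *same* regulatory SNP.  The
    truth set is the causal gene of each locus; bystanders are within
    1 Mb by construction.
    """
    start, spacing = 1_000_000, 2000
    blocks, genes, phenos = [], [], []
    for li in range(n_loci):
        chrom = str(li + 1)
        blocks.append(LdBlockSpec(n_snps=n_snps, rho=rho,
                                  maf_range=(0.1, 0.5), start_bp=start,
                                  spacing_bp=spacing, chrom=chrom))
        shared = snp_id_at(chrom, start, spacing, n_snps // 2)
        mid = start + (n_snps // 2) * spacing
        causal_gene = f"gene{li + 1}c"
        genes.append(GeneArchitecture(causal_gene, tss=mid, tes=mid + 5000,
                                      causal_snps=[(shared, 1.0)],
                                      h2=causal_h2, chrom=chrom))
        genes.append(GeneArchitecture(f"gene{li + 1}b1", tss=mid + 50_000,
                                      tes=mid + 55_000,
                                      causal_snps=[(shared, 1.0)],
                                      h2=bystander_h2, chrom=chrom))
        genes.append(GeneArchitecture(f"gene{li + 1}b2", tss=max(1, mid - 50_000),
                                      tes=max(1, mid - 50_000) + 5000,
                                      causal_snps=[(shared, -1.0)],
                                      h2=bystander_h2, chrom=chrom))
        phenos.append(PhenotypeArchitecture(f"pheno{li + 1}",
                                            mode="mediated_by_gene",
                                            gene_id=causal_gene,
                                            gene_effect=gene_effect))
    return ScenarioConfig(n_samples=n_samples, n_gwas_samples=n_gwas,
                          blocks=blocks, genes=genes, phenotypes=phenos,
                          seed=seed)


def truth_pairs_for(config: ScenarioConfig) -> set[tuple[str, str]]:
    """Gene-phenotype pairs that are causal by construction (mediation)."""
    return {(p.gene_id, p.phenotype_id) for p in config.phenotypes
            if p.mode == "mediated_by_gene" and p.gene_id}
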