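"""End-to-end orchestration: simulate -> preprocess -> eQTL -> models ->
TWAS -> conditional -> colocalization -> benchmark.

Stages hand off plain TSV files; every run writes a manifest recording
the seed and stage parameters, and re-running the same config is
bit-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark as bm
from . import coloc as cl
from . import conditional as cond
from . import eqtl as eq
from . import model_builder as mb
from . import preprocessing as pp
from . import synthetic as syn
from . import twas as tw
from .scenarios import bystander_benchmark_scenario, truth_pairs_for

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scenario: syn.ScenarioConfig
    seed: int = 0
    n_hidden_factors: int = 2
    min_reads: int = 6
    min_cpm: float = 1.0
    min_samples: int = 10
    eqtl_fdr: float = 0.01
    fit_fdr: float = 0.01
    twas_fdr: float = 0.01
    gwas_p: float = 5e-8
    clpp_threshold: float = 0.01
    conditional_alpha: float = 1e-5
    test_profile: bool = False
    dataset_id: str = "tissue1"

    def builder_profile(self) -> mb.BuilderProfile:
        return mb.BuilderProfile.test() if self.test_profile else mb.BuilderProfile.default()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sc = raw.pop("scenario")
        if isinstance(sc, str):
            if sc != "bystander_benchmark":
                raise ValueError(f"unknown named scenario {sc!r}")
            scenario = bystander_benchmark_scenario(
                seed=raw.get("seed", 0), **raw.pop("scenario_params", {}))
        else:
            scenario = scenario_from_dict(sc)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scenario, **raw)


def scenario_from_dict(d: dict) -> syn.ScenarioConfig:
    blocks = [syn.LdBlockSpec(**{**b, "maf_range": tuple(b.get("maf_range", (0.05, 0.5)))})
              for b in d["blocks"]]
    genes = [syn.GeneArchitecture(
        gene_id=g["gene_id"], tss=g["tss"], tes=g["tes"],
        causal_snps=[tuple(c) for c in g.get("causal_snps", [])],
        h2=g.get("h2", 0.0), chrom=str(g.get("chrom", "1")))
        for g in d.get("genes", [])]
    phenos = [syn.PhenotypeArchitecture(
        phenotype_id=p["phenotype_id"],
        causal_snps=[tuple(c) for c in p.get("causal_snps", [])],
        mode=p.get("mode", "distinct"), gene_id=p.get("gene_id"),
        gene_effect=p.get("gene_effect", 0.0))
        for p in d.get("phenotypes", [])]
    return syn.ScenarioConfig(
        n_samples=d["n_samples"], n_gwas_samples=d["n_gwas_samples"],
        blocks=blocks, genes=genes, phenotypes=phenos, seed=d.get("seed", 0))


def run(config: RunConfig, out_dir) -> bm.BenchmarkReport:
    """Execute every stage; returns the benchmark report.

    All intermediate tables are written under ``out_dir``; any stage
    failure propagates with the stage name prefixed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.scenario
    stage = "simulate"
    try:
        panel = syn.simulate_genotypes(sc, seed=config.seed)
        latent, counts = syn.simulate_expression_matrix(panel, sc.genes,
                                                        seed=config.seed + 1)
        annotations = syn.gene_annotation(sc.genes)
        syn.write_expression_tsv(counts, out / "counts.tsv")
        syn.write_annotation_bed(sc.genes, out / "genes.bed")
        gwas_by_pheno: dict[str, pd.DataFrame] = {}
        cohorts = {}
        for pi, ph in enumerate(sc.phenotypes):
            summ, cohort, _y = syn.simulate_gwas_summary(
                panel, ph, sc.genes, sc.n_gwas_samples,
                seed=config.seed + 101 + 13 * pi)
            gwas_by_pheno[ph.phenotype_id] = tw.harmonize(summ, panel)
            cohorts[ph.phenotype_id] = cohort
            syn.write_gwas_tsv(summ, out / f"gwas_{ph.phenotype_id}.tsv")

        stage = "preprocess"
        filtered = pp.filter_genes(counts, config.min_reads, config.min_cpm,
                                   min(config.min_samples, sc.n_samples))
        factors = pp.tmm_factors(filtered)
        logcpm = pp.log_cpm(filtered, factors)
        residual, _hidden = pp.remove_hidden_factors(
            logcpm, None, n_factors=config.n_hidden_factors)
        residual.to_csv(out / "residual_expression.tsv", sep="\t")

        stage = "eqtl"
        windows = eq.cis_windows(annotations[annotations.gene_id.isin(residual.index)])
        eqtl_records = eq.cis_scan(residual, panel, windows)
        eqtl_records.to_csv(out / "eqtl.tsv", sep="\t", index=False)

        stage = "build_models"
        models = mb.build_models(residual, panel, windows,
                                 profile=config.builder_profile(),
                                 seed=config.seed + 500)
        retained = mb.model_fit_qvalues(models, residual, panel,
                                        seed=config.seed + 600,
                                        fdr=config.fit_fdr)
        mb.models_table(models, panel).to_csv(out / "models.tsv", sep="\t",
                                              index=False)

        stage = "twas"
        ref = tw.LdReference(panel)
        results, twas_table = tw.association_scan(
            retained, gwas_by_pheno, ref, fdr=config.twas_fdr,
            dataset_id=config.dataset_id)
        twas_table.to_csv(out / "twas.tsv", sep="\t", index=False)

        stage = "conditional"
        models_by_gene = {m.gene_id: m for m in retained}
        cond_rows = []
        sig = twas_table[twas_table["significant"]]
        for row in sig.itertuples():
            if not row.top_contributing_snp:
                continue
            m = models_by_gene[row.gene_id]
            ct = cond.condition_and_retest(
                m, next(r for r in results
                        if r.gene_id == row.gene_id
                        and r.phenotype_id == row.phenotype_id),
                gwas_by_pheno[row.phenotype_id], ref, sc.n_gwas_samples,
                config.conditional_alpha, row.top_contributing_snp)
            ct["conditioned_on"] = row.top_contributing_snp
            cond_rows.append(ct)
        cond_table = (pd.concat(cond_rows, ignore_index=True)
                      if cond_rows else pd.DataFrame())
        cond_table.to_csv(out / "conditional.tsv", sep="\t", index=False)

        stage = "coloc"
        coloc_results = []
        for row in sig.itertuples():
            m = models_by_gene[row.gene_id]
            coloc_results.append(cl.colocalize_gene(
                m.snp_ids, row.gene_id, eqtl_records,
                gwas_by_pheno[row.phenotype_id], ref,
                phenotype_id=row.phenotype_id, dataset_id=config.dataset_id,
                eqtl_fdr=config.eqtl_fdr, gwas_p=config.gwas_p,
                threshold=config.clpp_threshold))
        coloc_calls = cl.call_colocalization(coloc_results,
                                             threshold=config.clpp_threshold)
        coloc_calls.to_csv(out / "coloc.tsv", sep="\t", index=False)

        stage = "benchmark"
        truth = bm.TruthSet(truth_pairs_for(sc), annotations)
        labeled = bm.annotate_bystanders(sig, truth, annotations)
        labeled.to_csv(out / "calls_labeled.tsv", sep="\t", index=False)
        report = bm.benchmark_report(labeled, truth, coloc_calls)
        (out / "benchmark.json").write_text(json.dumps(report.to_dict(), indent=2))

        manifest = {
            "seed": config.seed,
            "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                           if k != "scenario"},
            "scenario": {"n_samples": sc.n_samples,
                         "n_gwas_samples": sc.n_gwas_samples,
                         "n_blocks": len(sc.blocks), "n_genes": len(sc.genes),
                         "n_phenotypes": len(sc.phenotypes), "seed": sc.seed},
            "stages": ["simulate", "preprocess", "eqtl", "build_models",
                       "twas", "conditional", "coloc", "benchmark"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
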