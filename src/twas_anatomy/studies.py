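"""Reusable study designs measuring the pipeline's headline properties.

Each function simulates a synthetic study from scratch, runs the relevant
stages, and returns measured quantities: the exactness of the TWAS
decomposition, agreement of summary-based association with individual-
level oracles, the forward filter's R^2 guarantee, the multi-eQTL R^2
gain over the top eQTL, single-SNP dominance under conditioning, CLPP
scenario discrimination, FDR calibration under the null, and the
bystander-gene benchmark.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coloc as cl
from . import conditional as cond
from . import model_builder as mb
from . import pipeline as pl
from . import synthetic as syn
from . import twas as tw
from ._stats import marginal_ols
from .scenarios import bystander_benchmark_scenario, single_gene_scenario, snp_id_at


def _block_gwas_frame(cohort: syn.GenotypePanel, y: np.ndarray,
                      snp_idx: np.ndarray) -> pd.DataFrame:
    """Marginal summary statistics restricted to one block of a cohort."""
    X = cohort.dosages[:, snp_idx].astype(float)
    beta, se, _t, p, valid = marginal_ols(y, X)
    return pd.DataFrame({
        "SNP": cohort.snp_ids[snp_idx], "CHR": cohort.chroms[snp_idx],
        "BP": cohort.positions[snp_idx], "A1": cohort.a1[snp_idx],
        "A2": cohort.a2[snp_idx], "BETA": beta, "SE": se,
        "Z": beta / se, "P": p, "N": cohort.n_samples,
    })[valid]


# -- exactness checks ----------------------------------------------------

def twas_identity_error(seed: int, n_genes: int = 50) -> float:
    """Max |Z_g - Z_snp| over single-SNP models (formula-forced identity)."""
    rng = np.random.default_rng(seed)
    cfg = syn.ScenarioConfig(
        n_samples=300, n_gwas_samples=1000,
        blocks=[syn.LdBlockSpec(n_snps=n_genes, rho=0.4, maf_range=(0.1, 0.5),
                                start_bp=1_000_000)],
        seed=seed)
    panel = syn.simulate_genotypes(cfg)
    cohort = syn.resample_cohort(panel, 1000, seed=seed + 1)
    y = rng.standard_normal(1000)
    gwas = syn.gwas_summary_from_cohort(cohort, y).set_index("SNP")
    ref = tw.LdReference(panel)
    err = 0.0
    for j, snp in enumerate(panel.snp_ids):
        if snp not in gwas.index:
            continue
        w = float(rng.uniform(0.2, 2.0) * rng.choice([-1, 1]))
        m = mb.ExpressionModel(f"g{j}", [snp], {snp: w})
        res = tw.spredixcan_z(m, gwas, ref)
        zl = float(gwas.loc[snp, "Z"]) * np.sign(w)
        err = max(err, abs(res.z - zl))
    return err


def decomposition_error(seed: int, n_genes: int = 200) -> float:
    """Max |sum of per-SNP contributions - Z_g| over a multi-gene scan."""
    rng = np.random.default_rng(seed)
    cfg = syn.ScenarioConfig(
        n_samples=300, n_gwas_samples=1500,
        blocks=[syn.LdBlockSpec(n_snps=60, rho=0.6, maf_range=(0.1, 0.5),
                                start_bp=1_000_000)],
        seed=seed)
    panel = syn.simulate_genotypes(cfg)
    cohort = syn.resample_cohort(panel, 1500, seed=seed + 1)
    y = rng.standard_normal(1500)
    gwas = syn.gwas_summary_from_cohort(cohort, y)
    ref = tw.LdReference(panel)
    models = []
    for g in range(n_genes):
        k = int(rng.integers(1, 7))
        snps = list(rng.choice(panel.snp_ids, k, replace=False))
        models.append(mb.ExpressionModel(
            f"g{g}", snps, dict(zip(snps, rng.standard_normal(k)))))
    results, _table = tw.association_scan(models, {"pheno": gwas}, ref)
    return max(abs(sum(r.contributions.values()) - r.z) for r in results)


# -- multi-eQTL study: oracle agreement, filter guarantee, R^2 gain ------

@dataclass
class MultiEqtlStudy:
    records: pd.DataFrame  # one row per gene with all measured quantities

    @property
    def median_abs_delta(self) -> float:
        return float(self.records["abs_delta"].median())

    @property
    def filter_guarantee_ok(self) -> bool:
        r = self.records
        return bool(((r["r2_filtered"] >= 0.95 * r["r2_full"] - 1e-12)
                     & ~r["has_perfect_ld_pair"]).all())

    @property
    def median_fold_gain(self) -> float:
        return float(self.records["fold_gain"].median())


def multi_eqtl_study(seed: int, n_genes: int = 100, n_samples: int = 500,
                     n_gwas: int = 5000, h2: float = 0.5,
                     causal_idx: tuple[int, ...] = (2, 14, 26),
                     gene_effect: float = 0.06,
                     profile: mb.BuilderProfile | None = None) -> MultiEqtlStudy:
    """Genes with independent equal-effect causal cis-eQTLs, phenotypes
    mediated by genetic expression, and an independent GWAS cohort.

    Per gene, measures: the built model's r2_full / r2_filtered and
    whether any retained SNP pair is in perfect LD; cross-validated R^2 of
    the filtered model versus the top eQTL (fold gain); and the summary-
    statistic TWAS Z versus the individual-level Z from regressing the
    GWAS phenotype on predicted expression in the cohort.
    """
    profile = profile or mb.BuilderProfile.test()
    n_snps, start, spacing = 30, 1_000_000, 2000
    blocks, genes, phenos = [], [], []
    for gi in range(n_genes):
        chrom = str(gi + 1)
        blocks.append(syn.LdBlockSpec(n_snps=n_snps, rho=0.6,
                                      maf_range=(0.1, 0.5), start_bp=start,
                                      spacing_bp=spacing, chrom=chrom))
        causal = [(snp_id_at(chrom, start, spacing, j), 1.0) for j in causal_idx]
        mid = start + (n_snps // 2) * spacing
        genes.append(syn.GeneArchitecture(f"gene{gi}", tss=mid, tes=mid + 5000,
                                          causal_snps=causal, h2=h2, chrom=chrom))
        phenos.append(syn.PhenotypeArchitecture(
            f"pheno{gi}", mode="mediated_by_gene", gene_id=f"gene{gi}",
            gene_effect=gene_effect))
    cfg = syn.ScenarioConfig(n_samples=n_samples, n_gwas_samples=n_gwas,
                             blocks=blocks, genes=genes, phenotypes=phenos,
                             seed=seed)
    panel = syn.simulate_genotypes(cfg)
    cohort = syn.resample_cohort(panel, n_gwas, seed=seed + 77)
    ref = tw.LdReference(panel)

    rows = []
    for gi, (gene, pheno) in enumerate(zip(genes, phenos)):
        mask = panel.block_index == gi
        snp_idx = np.flatnonzero(mask)
        snps = list(panel.snp_ids[snp_idx])
        X = panel.dosages[:, snp_idx].astype(float)
        y = syn.simulate_expression(panel, gene, seed=seed * 331 + gi)
        model = mb.build_expression_model(
            gene.gene_id, y, X, snps, positions=panel.positions[snp_idx],
            profile=profile, seed=seed + 17 * gi)
        if model.n_snps == 0:
            continue
        kept_cols = [snps.index(s) for s in model.snp_ids]
        kept_r2 = panel.ld(model.snp_ids) ** 2 if model.n_snps > 1 else np.zeros((1, 1))
        np.fill_diagonal(kept_r2, 0)
        has_perfect = bool(kept_r2.max() >= 1.0 - 1e-10)

        # cross-validated R^2: filtered ridge model vs top-eQTL OLS
        cv_model = mb.cv_r2(y, X[:, kept_cols], model.ridge_alpha,
                            seed=seed + 3)
        _b, _se, _t, p_marg, _v = marginal_ols(y, X)
        top_col = int(np.nanargmin(p_marg))
        cv_top = mb.cv_r2(y, X[:, [top_col]], 0.0, seed=seed + 3)

        # summary-based vs individual-level association in the GWAS cohort
        y_ph = syn.simulate_phenotype(cohort, pheno, genes, seed=seed * 577 + gi)
        gwas = _block_gwas_frame(cohort, y_ph, snp_idx)
        res = tw.spredixcan_z(model, gwas.set_index("SNP"), ref)
        pred = cohort.dosage(model.snp_ids) @ model.weights_array()
        _bb, _ss, t_ind, _pp, _vv = marginal_ols(y_ph, pred[:, None])
        delta = abs(res.z - t_ind[0]) if res is not None else np.nan

        rows.append({
            "gene_id": gene.gene_id, "n_model_snps": model.n_snps,
            "r2_full": model.r2_full, "r2_filtered": model.r2_filtered,
            "has_perfect_ld_pair": has_perfect,
            "cv_r2_model": cv_model, "cv_r2_top_eqtl": cv_top,
            "fold_gain": cv_model / max(cv_top, 1e-6),
            "z_summary": np.nan if res is None else res.z,
            "z_individual": t_ind[0], "abs_delta": delta,
        })
    return MultiEqtlStudy(pd.DataFrame(rows))


# -- conditional oracle ---------------------------------------------------

def conditional_oracle_deltas(seed: int, n_snps_per_block: int = 50,
                              n_blocks: int = 10, n: int = 5000) -> np.ndarray:
    """|z_c - joint OLS t| per SNP with the reference equal to the cohort.

    The individual-level oracle fits, for every remaining SNP j, the OLS
    of the phenotype on [dosage_j, conditioning dosages] and takes j's
    t-statistic.
    """
    blocks = [syn.LdBlockSpec(n_snps=n_snps_per_block, rho=0.5,
                              maf_range=(0.1, 0.5), start_bp=1_000_000,
                              spacing_bp=2000, chrom=str(b + 1))
              for b in range(n_blocks)]
    cfg = syn.ScenarioConfig(n_samples=n, n_gwas_samples=n, blocks=blocks,
                             seed=seed)
    panel = syn.simulate_genotypes(cfg, n_samples=n)
    rng = np.random.default_rng(seed + 9)
    causal = [snp_id_at("1", 1_000_000, 2000, 5),
              snp_id_at("1", 1_000_000, 2000, 30),
              snp_id_at("2", 1_000_000, 2000, 12)]
    y = rng.standard_normal(n)
    for s, eff in zip(causal, (0.1, 0.08, 0.09)):
        x = panel.dosage([s])[:, 0]
        y = y + eff * (x - x.mean()) / x.std(ddof=1)
    gwas = syn.gwas_summary_from_cohort(panel, y)
    ref = tw.LdReference(panel)
    cond_set = causal[:2]
    cg = cond.condition_summary(gwas, ref, cond_set, n_gwas=n)
    Xs = panel.dosage(cond_set)
    Xs_c = np.column_stack([np.ones(n), Xs])
    deltas = []
    for row in cg.table.itertuples():
        if row.flags == "collinear":
            continue
        xj = panel.dosage([row.SNP])[:, 0]
        D = np.column_stack([np.ones(n), xj, Xs])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ coef
        df = n - D.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(D.T @ D)
        t_j = coef[1] / np.sqrt(cov[1, 1])
        deltas.append(abs(row.Z_C - t_j))
    return np.asarray(deltas)


# -- single-SNP dominance -------------------------------------------------

def dominance_rates(seed: int, n_seeds: int = 100, n_samples: int = 300,
                    n_gwas: int = 3000, alpha: float = 1e-5) -> dict:
    """Conditioning on the top contributing SNP: signal loss vs persistence.

    Arm one: a single causal eQTL mediates the phenotype -- conditioning
    should remove significance.  Arm two: two independent causal eQTLs --
    the residual signal should persist.  Returns the per-arm rates over
    seeds where the unconditioned TWAS was significant.
    """
    arms = {
        "single": {"causal_idx": (10,), "gene_effect": 0.12},
        "double": {"causal_idx": (3, 16), "gene_effect": 0.18},
    }
    out = {}
    for arm, spec in arms.items():
        removed = persisted = valid = 0
        for s in range(n_seeds):
            sd = seed * 1009 + s * 13 + (0 if arm == "single" else 7)
            sc = single_gene_scenario(
                n_samples=n_samples, n_gwas=n_gwas, n_snps=20, rho=0.6,
                h2=0.5, causal_idx=spec["causal_idx"],
                gene_effect=spec["gene_effect"], seed=sd)
            panel = syn.simulate_genotypes(sc)
            gene, pheno = sc.genes[0], sc.phenotypes[0]
            y = syn.simulate_expression(panel, gene, seed=sd + 1)
            model = mb.build_expression_model(
                gene.gene_id, y, panel.dosages.astype(float),
                list(panel.snp_ids), positions=panel.positions,
                profile=mb.BuilderProfile.fast(), seed=sd + 2)
            if model.n_snps == 0:
                continue
            gwas, _cohort, _yph = syn.simulate_gwas_summary(
                panel, pheno, sc.genes, n_gwas, seed=sd + 3)
            ref = tw.LdReference(panel)
            res = tw.spredixcan_z(model, gwas.set_index("SNP"), ref)
            if res is None or res.p > alpha:
                continue  # unconditioned signal absent; seed not informative
            try:
                top = tw.top_contributing_snp(res, ref)
            except ValueError:
                continue
            table = cond.condition_and_retest(model, res, gwas, ref, n_gwas,
                                              alpha, top)
            row = table.iloc[0]
            valid += 1
            still = row["status"] == "tested" and row["significant"]
            removed += not still
            persisted += bool(still)
        out[arm] = {
            "n_informative": valid,
            "removed_rate": removed / valid if valid else np.nan,
            "persist_rate": persisted / valid if valid else np.nan,
        }
    return out


# -- CLPP discrimination --------------------------------------------------

def clpp_discrimination(seed: int, n_loci: int = 100, m: int = 20,
                        rho: float = 0.5, ncp_true: float = 6.0,
                        threshold: float = 0.01) -> dict:
    """Shared- vs distinct-causal loci called at CLPP > threshold.

    Z vectors are drawn from the configuration model itself (mean
    ld @ lambda, covariance ld) with the true non-centrality at the causal
    SNPs, using LD estimated from a simulated panel block.
    """
    cfg = syn.ScenarioConfig(
        n_samples=1000, n_gwas_samples=1000,
        blocks=[syn.LdBlockSpec(n_snps=m, rho=rho, maf_range=(0.1, 0.5),
                                start_bp=1_000_000)],
        seed=seed)
    panel = syn.simulate_genotypes(cfg)
    ld = panel.ld(list(panel.snp_ids))
    L = np.linalg.cholesky(ld + 1e-10 * np.eye(m))
    r2 = ld**2
    rng = np.random.default_rng(seed + 5)

    def draw_z(causal_snp):
        lam = np.zeros(m)
        lam[causal_snp] = ncp_true
        return ld @ lam + L @ rng.standard_normal(m)

    shared_called = distinct_called = 0
    for _ in range(n_loci):
        i = int(rng.integers(0, m))
        z1, z2 = draw_z(i), draw_z(i)
        shared_called += cl.clpp(z1, z2, ld).max() > threshold
        # distinct causal pair with r^2 < 0.1
        while True:
            a, b = rng.integers(0, m, size=2)
            if a != b and r2[a, b] < 0.1:
                break
        z1, z2 = draw_z(int(a)), draw_z(int(b))
        distinct_called += cl.clpp(z1, z2, ld).max() > threshold
    return {
        "shared_called_rate": shared_called / n_loci,
        "distinct_called_rate": distinct_called / n_loci,
    }


# -- FDR calibration ------------------------------------------------------

def fdr_calibration(seed: int, n_null_genes: int = 500,
                    n_null_tests: int = 500, fdr: float = 0.01) -> dict:
    """False-retention rates under the null for model fit and association."""
    cfg = syn.ScenarioConfig(
        n_samples=300, n_gwas_samples=1000,
        blocks=[syn.LdBlockSpec(n_snps=30, rho=0.3, maf_range=(0.1, 0.5),
                                start_bp=1_000_000)],
        seed=seed)
    panel = syn.simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)

    # null expression: genes with no genetic component, arbitrary 2-SNP models
    expr = pd.DataFrame(rng.standard_normal((n_null_genes, panel.n_samples)),
                        index=[f"g{i}" for i in range(n_null_genes)])
    models = []
    for i in range(n_null_genes):
        snps = list(rng.choice(panel.snp_ids, 2, replace=False))
        models.append(mb.ExpressionModel(
            f"g{i}", snps, dict(zip(snps, rng.standard_normal(2))),
            ridge_alpha=50.0))
    kept = mb.model_fit_qvalues(models, expr, panel, seed=seed + 2, fdr=fdr)
    fit_rate = len(kept) / n_null_genes

    # null association scan: models x null phenotypes
    n_models = 100
    n_phenos = int(np.ceil(n_null_tests / n_models))
    scan_models = []
    for i in range(n_models):
        snps = list(rng.choice(panel.snp_ids, 3, replace=False))
        scan_models.append(mb.ExpressionModel(
            f"m{i}", snps, dict(zip(snps, rng.standard_normal(3)))))
    cohort = syn.resample_cohort(panel, 1000, seed=seed + 3)
    gwas_by_pheno = {
        f"null{j}": syn.gwas_summary_from_cohort(
            cohort, rng.standard_normal(1000))
        for j in range(n_phenos)
    }
    _res, table = tw.association_scan(scan_models, gwas_by_pheno,
                                      tw.LdReference(panel), fdr=fdr)
    assoc_rate = float(table["significant"].mean())
    return {"model_fit_false_retention": fit_rate,
            "association_false_retention": assoc_rate,
            "n_fit_nulls": n_null_genes, "n_assoc_nulls": len(table)}


# -- bystander benchmark --------------------------------------------------

def bystander_benchmark(seed: int, out_dir, n_loci: int = 20,
                        n_samples: int = 500, n_gwas: int = 3000):
    """Full-pipeline benchmark with pleiotropic shared-eQTL bystanders."""
    sc = bystander_benchmark_scenario(n_loci=n_loci, n_samples=n_samples,
                                      n_gwas=n_gwas, seed=seed)
    config = pl.RunConfig(scenario=sc, seed=seed, test_profile=True)
    return pl.run(config, out_dir)
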