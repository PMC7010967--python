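"""Generator correctness: LD structure, heritability scaling, GWAS summaries."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twas_anatomy import synthetic as syn
from twas_anatomy._stats import marginal_ols
from twas_anatomy.scenarios import single_gene_scenario, snp_id_at


def _two_block_config(rho, n_snps=10, n=2000, seed=0):
    return syn.ScenarioConfig(
        n_samples=n, n_gwas_samples=500,
        blocks=[
            syn.LdBlockSpec(n_snps=n_snps, rho=rho, maf_range=(0.1, 0.5),
                            start_bp=1_000_000, chrom="1"),
            syn.LdBlockSpec(n_snps=n_snps, rho=rho, maf_range=(0.1, 0.5),
                            start_bp=1_000_000, chrom="2"),
        ],
        seed=seed,
    )


class TestGenotypes:
    def test_cross_block_independence(self):
        panel = syn.simulate_genotypes(_two_block_config(rho=0.0, n=2000))
        X = panel.dosages.astype(float)
        r = np.corrcoef(X, rowvar=False)
        cross = r[:10, 10:]
        assert np.abs(cross).max() < 0.1

    def test_high_rho_gives_high_adjacent_r2(self):
        cfg = syn.ScenarioConfig(
            n_samples=2000, n_gwas_samples=500,
            blocks=[syn.LdBlockSpec(n_snps=10, rho=0.95, maf_range=(0.1, 0.5),
                                    start_bp=1_000_000)],
            seed=1)
        panel = syn.simulate_genotypes(cfg)
        r = panel.ld(list(panel.snp_ids))
        adj_r2 = np.array([r[i, i + 1] ** 2 for i in range(panel.n_snps - 1)])
        assert adj_r2.max() > 0.5

    def test_seeded_determinism(self):
        cfg = _two_block_config(rho=0.5, n=300, seed=9)
        p1 = syn.simulate_genotypes(cfg)
        p2 = syn.simulate_genotypes(cfg)
        assert np.array_equal(p1.dosages, p2.dosages)
        assert list(p1.snp_ids) == list(p2.snp_ids)

    def test_realized_maf_floor(self):
        cfg = syn.ScenarioConfig(
            n_samples=200, n_gwas_samples=500,
            blocks=[syn.LdBlockSpec(n_snps=30, rho=0.3, maf_range=(0.05, 0.2),
                                    start_bp=1_000_000)],
            seed=2)
        panel = syn.simulate_genotypes(cfg)
        assert panel.maf.min() >= 0.05

    def test_degenerate_configs_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.LdBlockSpec(n_snps=0).validate()
        with pytest.raises(syn.ConfigError):
            syn.LdBlockSpec(n_snps=5, rho=1.0).validate()
        with pytest.raises(syn.ConfigError):
            syn.ScenarioConfig(n_samples=49, n_gwas_samples=100,
                               blocks=[syn.LdBlockSpec(n_snps=5)]).validate()
        with pytest.raises(syn.ConfigError):
            syn.LdBlockSpec(n_snps=5, maf_range=(0.01, 0.5)).validate()


class TestExpression:
    def test_null_heritability_has_no_genetic_signal(self, small_panel):
        snp = small_panel.snp_ids[3]
        gene = syn.GeneArchitecture("g", tss=1_000_000, tes=1_005_000,
                                    causal_snps=[(snp, 1.0)], h2=0.0)
        hits = 0
        for seed in range(40):
            y = syn.simulate_expression(small_panel, gene, seed=seed)
            _b, _se, t, _p, _v = marginal_ols(y, small_panel.dosage([snp]))
            hits += abs(t[0]) < 4
        assert hits >= 38  # |t| < 4 in >= 95% of seeds

    def test_h2_sets_explained_variance(self):
        sc = single_gene_scenario(n_samples=500, h2=0.5, causal_idx=(14,), seed=4)
        panel = syn.simulate_genotypes(sc)
        gene = sc.genes[0]
        snp = gene.causal_snps[0][0]
        x = panel.dosage([snp])[:, 0]
        in_band = 0
        for seed in range(60):
            y = syn.simulate_expression(panel, gene, seed=seed)
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            in_band += 0.35 <= r2 <= 0.65
        assert in_band >= 54  # within [0.35, 0.65] in >= 90% of seeds

    def test_equal_effects_split_h2(self):
        # two uncorrelated causal SNPs, equal effects -> marginal R^2 ~ h2/2
        sc = single_gene_scenario(n_samples=4000, h2=0.5, rho=0.0,
                                  causal_idx=(2, 20), seed=6)
        panel = syn.simulate_genotypes(sc)
        gene = sc.genes[0]
        y = syn.simulate_expression(panel, gene, seed=0)
        for snp, _e in gene.causal_snps:
            x = panel.dosage([snp])[:, 0]
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            assert abs(r2 - 0.25) < 0.06

    def test_missing_causal_snp_errors(self, small_panel):
        gene = syn.GeneArchitecture("g", tss=1, tes=2,
                                    causal_snps=[("nope", 1.0)], h2=0.3)
        with pytest.raises(KeyError):
            syn.simulate_expression(small_panel, gene, seed=0)

    def test_counts_are_nonnegative_and_seeded(self, small_panel):
        gene = syn.GeneArchitecture("g", tss=1_000_000, tes=1_005_000,
                                    causal_snps=[(small_panel.snp_ids[0], 1.0)],
                                    h2=0.3)
        lat1, c1 = syn.simulate_expression_matrix(small_panel, [gene], seed=3)
        _lat2, c2 = syn.simulate_expression_matrix(small_panel, [gene], seed=3)
        assert (c1.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(c1, c2)


class TestGwasSummary:
    def test_null_phenotype_p_uniformity(self):
        cfg = syn.ScenarioConfig(
            n_samples=50, n_gwas_samples=2000,
            blocks=[syn.LdBlockSpec(n_snps=2000, rho=0.0, maf_range=(0.1, 0.5),
                                    start_bp=1_000_000, spacing_bp=100)],
            seed=3)
        pheno = syn.PhenotypeArchitecture("null", mode="distinct")
        panel = syn.simulate_genotypes(cfg, n_samples=50)
        summ, _c, _y = syn.simulate_gwas_summary(panel, pheno, [], 2000, seed=5)
        frac = (summ["P"] < 0.05).mean()
        assert abs(frac - 0.05) <= 0.02

    def test_powered_snp_reaches_genome_wide_significance(self):
        # effect for expected chi2 ncp 64: beta = 8/sqrt(n) on standardized dosage
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            sc = single_gene_scenario(n_samples=100, n_gwas=2000, rho=0.0,
                                      seed=seed)
            panel = syn.simulate_genotypes(sc)
            snp = snp_id_at("1", 1_000_000, 2000, 5)
            pheno = syn.PhenotypeArchitecture(
                "p", causal_snps=[(snp, 8.0 / np.sqrt(2000))], mode="distinct")
            summ, _c, _y = syn.simulate_gwas_summary(panel, pheno, [], 2000,
                                                     seed=1000 + seed)
            p = summ.set_index("SNP").loc[snp, "P"]
            hits += p <= 5.0e-8
        # analytic power of chi2(1, ncp=64) at the genome-wide threshold ~ 0.94
        assert hits >= int(0.7 * n_seeds)

    def test_summary_matches_ols_oracle(self, small_panel):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        y = rng.standard_normal(small_panel.n_samples)
        summ = syn.gwas_summary_from_cohort(small_panel, y)
        for row in summ.sample(5, random_state=1).itertuples():
            x = small_panel.dosage([row.SNP])[:, 0]
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert abs(fit.params[1] - row.BETA) < 1e-10
            assert abs(fit.bse[1] - row.SE) < 1e-10

    def test_monomorphic_snps_excluded(self, small_panel):
        cohort = syn.GenotypePanel(
            np.column_stack([small_panel.dosages[:, 0],
                             np.ones(small_panel.n_samples, dtype=np.int8)]),
            ["a", "b"], ["1", "1"], [1, 2], ["A", "A"], ["G", "G"],
            [0.3, 0.3], [0, 0], [])
        y = np.random.default_rng(1).standard_normal(small_panel.n_samples)
        summ = syn.gwas_summary_from_cohort(cohort, y)
        assert list(summ["SNP"]) == ["a"]

    def test_gwas_cohort_independent_of_panel(self, small_panel):
        cohort = syn.resample_cohort(small_panel, 400, seed=99)
        assert not np.array_equal(cohort.dosages, small_panel.dosages)
        # same LD model: adjacent correlation of block 1 is similar
        r_panel = small_panel.ld(list(small_panel.snp_ids[:12]))
        r_cohort = cohort.ld(list(cohort.snp_ids[:12]))
        adj_p = np.array([r_panel[i, i + 1] for i in range(11)])
        adj_c = np.array([r_cohort[i, i + 1] for i in range(11)])
        assert abs(adj_p.mean() - adj_c.mean()) < 0.15


class TestWriters:
    def test_bed_round_trip(self, tmp_path):
        genes = [syn.GeneArchitecture("g1", tss=100, tes=500, chrom="2")]
        path = tmp_path / "genes.bed"
        syn.write_annotation_bed(genes, path)
        ann = syn.read_annotation_bed(path)
        assert ann.loc[0, "tss"] == 100 and ann.loc[0, "tes"] == 500

    def test_genotype_tsv_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "geno.tsv"
        syn.write_genotypes_tsv(small_panel, path)
        back = syn.read_genotypes_tsv(path)
        assert np.array_equal(back.dosages, small_panel.dosages)
        assert list(back.snp_ids) == list(small_panel.snp_ids)

    def test_vcf_is_parseable(self, tmp_path, small_panel):
        from cyvcf2 import VCF
        path = tmp_path / "geno.vcf"
        syn.write_genotypes_vcf(small_panel, path)
        variants = list(VCF(str(path)))
        assert len(variants) == small_panel.n_snps
        gt_dosage = np.array([v.gt_types for v in variants])
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 3=hom-alt
        mapped = np.where(gt_dosage == 3, 2, gt_dosage).T
        assert np.array_equal(mapped, small_panel.dosages)

    def test_gwas_tsv_header(self, tmp_path, small_panel):
        y = np.random.default_rng(2).standard_normal(small_panel.n_samples)
        summ = syn.gwas_summary_from_cohort(small_panel, y)
        path = tmp_path / "gwas.tsv"
        syn.write_gwas_tsv(summ, path)
        header = open(path).readline().rstrip("\n").split("\t")
        assert header[:7] == ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE"]
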