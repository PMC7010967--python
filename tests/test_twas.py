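"""S-PrediXcan Z computation, harmonization, and decomposition."""
import numpy as np
import pandas as pd
import pytest

from twas_anatomy import synthetic as syn, twas
from twas_anatomy.model_builder import ExpressionModel


def _gwas_frame(panel, snps=None, z=None, seed=0):
    rng = np.random.default_rng(seed)
    snps = list(panel.snp_ids) if snps is None else snps
    idx = panel.indices(snps)
    se = rng.uniform(0.02, 0.1, len(snps))
    zval = rng.standard_normal(len(snps)) if z is None else np.asarray(z, float)
    return pd.DataFrame({
        "SNP": snps, "CHR": panel.chroms[idx], "BP": panel.positions[idx],
        "A1": panel.a1[idx], "A2": panel.a2[idx],
        "BETA": zval * se, "SE": se, "Z": zval,
        "P": 1.0, "N": 1000,
    })


class TestHarmonize:
    def test_matched_alleles_identity(self, small_panel):
        gwas = _gwas_frame(small_panel)
        out = twas.harmonize(gwas, small_panel)
        pd.testing.assert_frame_equal(out, gwas)

    def test_swapped_alleles_flip_sign(self, small_panel):
        gwas = _gwas_frame(small_panel)
        gwas.loc[0, ["A1", "A2"]] = [gwas.loc[0, "A2"], gwas.loc[0, "A1"]]
        gwas.loc[0, "BETA"] = 0.2
        out = twas.harmonize(gwas, small_panel)
        assert out.loc[0, "BETA"] == pytest.approx(-0.2)
        assert out.loc[0, "SE"] == gwas.loc[0, "SE"]

    def test_ambiguous_snp_dropped(self, small_panel):
        gwas = _gwas_frame(small_panel)
        gwas.loc[3, ["A1", "A2"]] = ["A", "T"]
        out = twas.harmonize(gwas, small_panel)
        assert gwas.loc[3, "SNP"] not in set(out["SNP"])

    def test_mismatched_alleles_dropped(self, small_panel):
        gwas = _gwas_frame(small_panel)
        gwas.loc[5, ["A1", "A2"]] = ["A", "C"]
        if (small_panel.a1[5], small_panel.a2[5]) != ("A", "C"):
            out = twas.harmonize(gwas, small_panel)
            assert gwas.loc[5, "SNP"] not in set(out["SNP"])


class TestSigmaG:
    def test_single_snp_scaling(self, small_panel):
        snp = small_panel.snp_ids[0]
        ref = twas.LdReference(small_panel)
        m = ExpressionModel("g", [snp], {snp: 2.0})
        assert twas.sigma_g(m, ref) == pytest.approx(2.0 * ref.sigma([snp])[0])

    def test_matches_direct_sd_of_predicted_expression(self, small_panel):
        rng = np.random.default_rng(3)
        snps = list(rng.choice(small_panel.snp_ids, 5, replace=False))
        w = rng.standard_normal(5)
        m = ExpressionModel("g", snps, dict(zip(snps, w)))
        ref = twas.LdReference(small_panel)
        direct = (small_panel.dosage(snps) @ w).std(ddof=1)
        assert twas.sigma_g(m, ref) == pytest.approx(direct, abs=1e-8)

    def test_orthogonal_sum(self):
        # two uncorrelated unit-variance SNPs with unit weights -> sqrt(2)
        class FakeRef:
            def cov(self, ids):
                return np.eye(2)

            def sigma(self, ids):
                return np.ones(2)

        m = ExpressionModel("g", ["a", "b"], {"a": 1.0, "b": 1.0})
        assert twas.sigma_g(m, FakeRef()) == pytest.approx(np.sqrt(2))


class TestSpredixcanZ:
    def test_single_snp_model_z_identity(self, small_panel):
        ref = twas.LdReference(small_panel)
        for w in (0.7, 2.0):
            snp = small_panel.snp_ids[4]
            m = ExpressionModel("g", [snp], {snp: w})
            gwas = _gwas_frame(small_panel, seed=1)
            res = twas.spredixcan_z(m, gwas, ref)
            zl = gwas.set_index("SNP").loc[snp, "Z"]
            assert res.z == pytest.approx(zl, abs=1e-12)

    def test_negative_weight_flips_sign(self, small_panel):
        ref = twas.LdReference(small_panel)
        snp = small_panel.snp_ids[4]
        gwas = _gwas_frame(small_panel, seed=1)
        zl = gwas.set_index("SNP").loc[snp, "Z"]
        m = ExpressionModel("g", [snp], {snp: -1.3})
        res = twas.spredixcan_z(m, gwas, ref)
        assert res.z == pytest.approx(-zl, abs=1e-12)

    def test_contributions_sum_to_z(self, small_panel, rng):
        ref = twas.LdReference(small_panel)
        snps = list(rng.choice(small_panel.snp_ids, 6, replace=False))
        m = ExpressionModel("g", snps, dict(zip(snps, rng.standard_normal(6))))
        res = twas.spredixcan_z(m, _gwas_frame(small_panel, seed=2), ref)
        assert sum(res.contributions.values()) == pytest.approx(res.z, abs=1e-10)

    def test_allele_flip_invariance(self, small_panel, rng):
        ref = twas.LdReference(small_panel)
        snps = list(rng.choice(small_panel.snp_ids, 4, replace=False))
        m = ExpressionModel("g", snps, dict(zip(snps, rng.standard_normal(4))))
        gwas = _gwas_frame(small_panel, seed=5)
        z0 = twas.spredixcan_z(m, gwas, ref).z
        flipped = gwas.copy()
        row = flipped["SNP"] == snps[0]
        flipped.loc[row, ["A1", "A2"]] = flipped.loc[row, ["A2", "A1"]].to_numpy()
        flipped.loc[row, ["BETA", "Z"]] *= -1.0
        z1 = twas.spredixcan_z(m, twas.harmonize(flipped, small_panel), ref).z
        assert z1 == pytest.approx(z0, abs=1e-12)

    def test_missing_snp_reduces_coverage(self, small_panel, rng):
        ref = twas.LdReference(small_panel)
        snps = list(small_panel.snp_ids[:4])
        m = ExpressionModel("g", snps, dict(zip(snps, np.ones(4))))
        gwas = _gwas_frame(small_panel, snps=snps[:2], seed=3)
        res = twas.spredixcan_z(m, gwas, ref)
        assert res.coverage == pytest.approx(0.5)

    def test_zero_coverage_gives_no_result(self, small_panel):
        ref = twas.LdReference(small_panel)
        snps = list(small_panel.snp_ids[:2])
        m = ExpressionModel("g", snps, dict(zip(snps, np.ones(2))))
        gwas = _gwas_frame(small_panel, snps=list(small_panel.snp_ids[5:8]))
        assert twas.spredixcan_z(m, gwas, ref) is None


class TestTopContributingSnp:
    def _result(self, contributions, z):
        return twas.TwasResult("g", "p", "d", z, 0.5, 1.0, contributions, 1.0,
                               len(contributions))

    def test_same_sign_max_magnitude(self, small_panel):
        ref = twas.LdReference(small_panel)
        s = list(small_panel.snp_ids[:3])
        res = self._result({s[0]: 1.5, s[1]: -0.4, s[2]: 0.9}, z=2.0)
        assert twas.top_contributing_snp(res, ref) == s[0]

    def test_tie_broken_by_position(self, small_panel):
        ref = twas.LdReference(small_panel)
        s = [small_panel.snp_ids[2], small_panel.snp_ids[0]]
        res = self._result({s[0]: 1.0, s[1]: 1.0}, z=2.0)
        assert twas.top_contributing_snp(res, ref) == small_panel.snp_ids[0]

    def test_no_same_sign_contribution_errors(self, small_panel):
        ref = twas.LdReference(small_panel)
        s = list(small_panel.snp_ids[:2])
        res = self._result({s[0]: -1.0, s[1]: -0.5}, z=0.2)
        with pytest.raises(ValueError):
            twas.top_contributing_snp(res, ref)


class TestAssociationScan:
    def test_duplicate_phenotype_deterministic(self, small_panel, rng):
        ref = twas.LdReference(small_panel)
        snps = list(small_panel.snp_ids[:3])
        m = ExpressionModel("g", snps, dict(zip(snps, rng.standard_normal(3))))
        gwas = _gwas_frame(small_panel, seed=9)
        _res, table = twas.association_scan([m], {"p1": gwas, "p2": gwas.copy()},
                                            ref)
        z = table.set_index("phenotype_id")["z"]
        assert z["p1"] == z["p2"]
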