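import numpy as np
import pytest

from twas_anatomy import synthetic as syn


@pytest.fixture(scope="session")
def small_panel():
    """Two-block panel (rho 0.6 / 0.0), 24 SNPs, 400 samples."""
    cfg = syn.ScenarioConfig(
        n_samples=400, n_gwas_samples=1000,
        blocks=[
            syn.LdBlockSpec(n_snps=12, rho=0.6, maf_range=(0.1, 0.5),
                            start_bp=1_000_000, spacing_bp=2000, chrom="1"),
            syn.LdBlockSpec(n_snps=12, rho=0.0, maf_range=(0.1, 0.5),
                            start_bp=5_000_000, spacing_bp=2000, chrom="1"),
        ],
        seed=7,
    )
    return syn.simulate_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
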