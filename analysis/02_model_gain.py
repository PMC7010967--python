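"""Multi-SNP expression models vs the top eQTL.

Simulates 100 genes with three independent causal cis-eQTLs (h2 = 0.5,
n = 500), builds LASSO -> forward-filter -> ridge models, and compares
cross-validated R^2 against the single top eQTL.  Also verifies the
forward filter's training guarantee (subset R^2 >= 95% of the full
model's) and the absence of retained perfect-LD pairs.
"""
from pathlib import Path

from twas_anatomy import studies

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    study = studies.multi_eqtl_study(seed=1, n_genes=100)
    OUT.mkdir(exist_ok=True)
    study.records.to_csv(OUT / "model_gain.tsv", sep="\t", index=False)
    r = study.records
    print(f"genes modeled: {len(r)}")
    print(f"median model size: {r['n_model_snps'].median():.0f} SNPs")
    print(f"median CV-R^2, filtered model: {r['cv_r2_model'].median():.3f}")
    print(f"median CV-R^2, top eQTL:       {r['cv_r2_top_eqtl'].median():.3f}")
    print(f"median fold gain: {study.median_fold_gain:.2f}")
    print(f"filter guarantee holds for all genes: {study.filter_guarantee_ok}")
    print(f"summary-vs-individual TWAS |dZ| median: {study.median_abs_delta:.3f}")
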