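"""Sensitivity / PPV benchmarking of TWAS calls against a causal truth set.

Significant gene-phenotype calls are labeled ``true_positive`` (the pair
is in the truth set), ``bystander`` (the gene lies within 1 Mb of a truth
gene for the same phenotype -- minimal gene-body to gene-body distance,
closed interval), or ``novel``.  Sensitivity is |detected truth pairs| /
|truth set|; PPV is TP / (TP + bystanders) over unique gene-phenotype
pairs at truth loci, optionally restricted to colocalized calls.
Specificity is deliberately not computed: the true-negative universe
would rest on arbitrary locus-definition assumptions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

BYSTANDER_WINDOW = 1_000_000


@dataclass
class TruthSet:
    """Causal gene-phenotype pairs plus gene coordinates."""

    pairs: set[tuple[str, str]]
    coordinates: pd.DataFrame  # gene_id, chrom, tss, tes

    def __post_init__(self):
        known = set(self.coordinates["gene_id"])
        missing = {g for g, _ in self.pairs} - known
        if missing:
            raise ValueError(f"truth genes missing coordinates: {sorted(missing)}")

    @classmethod
    def from_tables(cls, pairs: pd.DataFrame, annotations: pd.DataFrame) -> "TruthSet":
        return cls(set(zip(pairs["gene_id"], pairs["phenotype_id"])), annotations)


def _gene_body_distance(a: pd.Series, b: pd.Series) -> float:
    if str(a["chrom"]) != str(b["chrom"]):
        return np.inf
    if a["tes"] < b["tss"]:
        return b["tss"] - a["tes"]
    if b["tes"] < a["tss"]:
        return a["tss"] - b["tes"]
    return 0  # overlapping bodies


def annotate_bystanders(calls: pd.DataFrame, truth: TruthSet,
                        annotations: pd.DataFrame,
                        window: int = BYSTANDER_WINDOW,
                        distance: str = "gene_body") -> pd.DataFrame:
    """Label significant calls as true_positive / bystander / novel.

    ``distance`` may be ``gene_body`` (default) or ``tss`` (TSS-to-TSS).
    Calls on genes without coordinates are labeled novel (warned via the
    returned ``unannotated`` flag column).
    """
    coords = annotations.set_index("gene_id")
    truth_coords = truth.coordinates.set_index("gene_id")
    truth_by_pheno: dict[str, list[str]] = {}
    for g, ph in truth.pairs:
        truth_by_pheno.setdefault(ph, []).append(g)
    labels, unannot = [], []
    for row in calls.itertuples():
        pair = (row.gene_id, row.phenotype_id)
        if pair in truth.pairs:
            labels.append("true_positive")
            unannot.append(False)
            continue
        if row.gene_id not in coords.index:
            labels.append("novel")
            unannot.append(True)
            continue
        g = coords.loc[row.gene_id]
        near = False
        for tg in truth_by_pheno.get(row.phenotype_id, []):
            t = truth_coords.loc[tg]
            if distance == "tss":
                d = np.inf if str(g["chrom"]) != str(t["chrom"]) else abs(g["tss"] - t["tss"])
            else:
                d = _gene_body_distance(g, t)
            if d <= window:
                near = True
                break
        labels.append("bystander" if near else "novel")
        unannot.append(False)
    out = calls.copy()
    out["label"] = labels
    out["unannotated"] = unannot
    return out


def sensitivity(truth: TruthSet, detected: set[tuple[str, str]]) -> float:
    """Fraction of truth pairs detected."""
    if not truth.pairs:
        raise ValueError("truth set is empty")
    return len(detected & truth.pairs) / len(truth.pairs)


def ppv(n_true_positive: int, n_bystander: int) -> float:
    """TP / (TP + bystanders) over unique pairs at truth loci; NA if none."""
    denom = n_true_positive + n_bystander
    if denom == 0:
        return float("nan")
    return n_true_positive / denom


@dataclass
class BenchmarkReport:
    sensitivity: float
    ppv: float
    ppv_colocalized: float
    n_truth: int
    n_true_positive: int
    n_bystander: int
    n_novel: int
    n_true_positive_coloc: int
    n_bystander_coloc: int
    detected_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["detected_pairs"] = [list(p) for p in self.detected_pairs]
        return d


def benchmark_report(labeled_calls: pd.DataFrame, truth: TruthSet,
                     coloc_calls: pd.DataFrame | None = None) -> BenchmarkReport:
    """Summarize labeled calls into sensitivity / PPV, deduplicating
    gene-phenotype pairs across datasets."""
    uniq = labeled_calls.drop_duplicates(["gene_id", "phenotype_id"])
    tp_pairs = {(r.gene_id, r.phenotype_id) for r in uniq.itertuples()
                if r.label == "true_positive"}
    by_pairs = {(r.gene_id, r.phenotype_id) for r in uniq.itertuples()
                if r.label == "bystander"}
    nv = int((uniq["label"] == "novel").sum())
    coloc_ok: set[tuple[str, str]] = set()
    if coloc_calls is not None and not coloc_calls.empty:
        coloc_ok = {(r.gene_id, r.phenotype_id) for r in coloc_calls.itertuples()
                    if r.call == "colocalized"}
    tp_c = len(tp_pairs & coloc_ok)
    by_c = len(by_pairs & coloc_ok)
    return BenchmarkReport(
        sensitivity=sensitivity(truth, tp_pairs),
        ppv=ppv(len(tp_pairs), len(by_pairs)),
        ppv_colocalized=ppv(tp_c, by_c),
        n_truth=len(truth.pairs),
        n_true_positive=len(tp_pairs),
        n_bystander=len(by_pairs),
        n_novel=nv,
        n_true_positive_coloc=tp_c,
        n_bystander_coloc=by_c,
        detected_pairs=sorted(tp_pairs),
    )


def load_truth_detections() -> pd.DataFrame:
    """Packaged reference table of detected causal gene-metabolite
    associations (curated truth-set hits), used for report-format
    regression tests."""
    with resources.files("twas_anatomy.data").joinpath(
            "truth_set_detections.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
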