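"""CLPP discrimination between shared and distinct causal configurations.

Draws per-locus Z vectors from the configuration model (mean ld @ lambda,
covariance ld) for loci where the two traits share one causal SNP versus
loci where the causal SNPs are distinct (r^2 < 0.1), and reports how
often each arm is called colocalized at CLPP > 0.01.
"""
import json
from pathlib import Path

from twas_anatomy import studies

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    rates = studies.clpp_discrimination(seed=1, n_loci=100)
    print(f"shared-causal loci called colocalized: "
          f"{rates['shared_called_rate']:.2f}")
    print(f"distinct-causal loci called colocalized: "
          f"{rates['distinct_called_rate']:.2f}")
    OUT.mkdir(exist_ok=True)
    (OUT / "clpp_discrimination.json").write_text(json.dumps(rates, indent=2))
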