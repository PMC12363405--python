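#!/usr/bin/env python
"""Quantify UMI-consensus error suppression on a variant-free sample.

Simulates reads at per-base error 0.003, collapses UMI families (minimum
size 3, 2/3 majority) and compares the raw mismatch rate with the pooled
post-consensus alt rate at 100 variant-free positions.
"""

from pathlib import Path

import pandas as pd

from ctdna_mrd import studies

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    res = studies.error_suppression_study(seed=1)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame([res]).to_csv(OUT / "error_suppression.tsv", sep="\t", index=False)
    print(f"raw per-base mismatch rate:  {res['raw_error_rate']:.2e}")
    print(f"post-consensus background:   {res['post_consensus_rate']:.2e} "
          f"({res['alt_molecules']} alt molecules over {res['molecule_sites']} "
          f"molecule-site observations)")
    print(f"suppression: {res['suppression_fold']:.0f}-fold")
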