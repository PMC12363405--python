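#!/usr/bin/env python
"""Phased-variant detection across the 100 bp cis window.

Plants cis pairs at 40/80/100 bp (inside the window) and one variant pair
102 bp apart (outside), then checks recovery and that no out-of-window
pair is evaluated.
"""

from pathlib import Path

import pandas as pd

from ctdna_mrd import studies

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    res = studies.phasing_study(seed=1)
    rows = [
        {"pos_a": p.pos_a, "pos_b": p.pos_b, "distance": p.pos_b - p.pos_a,
         "support": p.support, "covering": p.covering}
        for p in res["detected"]
    ]
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "phasing.tsv", sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"planted cis pairs recovered: {res['recovered_pairs']}/{res['planted_pairs']}")
    print(f"pairs evaluated beyond 100 bp: {res['beyond_window_detected']}")
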