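#!/usr/bin/env python
"""Generate the simulated study: reads, truth tables, cohort and sidecars.

Writes a complete fixture dataset (4 read-level patients x 4 timepoints,
a 17-patient clinical cohort with the designed EMR/response structure, a
CNV sample with panel-of-normals sidecars, germline VCFs, BEDs and a YAML
run config) under scratch/fixtures.
"""

from pathlib import Path

import pandas as pd

import ctdna_mrd as cm

OUT = Path(__file__).resolve().parents[1] / "scratch" / "fixtures"

if __name__ == "__main__":
    cm.make_fixtures(seed=1, out_dir=OUT)
    cohort = pd.read_csv(OUT / "cohort.csv", keep_default_na=False)
    print(f"fixtures written to {OUT}")
    print(f"cohort: {len(cohort)} patients, {cohort['emr'].sum()} with EMR")
    print(cohort.groupby("emr")["eot_response"].value_counts())
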