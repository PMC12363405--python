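#!/usr/bin/env python
"""Run the full pipeline over the simulated study and summarise its outputs.

Consumes scratch/fixtures (see 01_make_fixtures.py) and writes the stage
tables — variant calls, burden/EMR quantification, MRD calls, CNV
segments, identity QC, the outcomes bundle and the longitudinal ribbon
table — under results/pipeline.
"""

from pathlib import Path

import ctdna_mrd as cm
from ctdna_mrd.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "scratch" / "fixtures"

if __name__ == "__main__":
    if not FIX.exists():
        raise SystemExit("run analysis/01_make_fixtures.py first")
    config = RunConfig.from_yaml(FIX / "config.yaml")
    config.output_dir = str(ROOT / "results" / "pipeline")
    out = cm.run_pipeline(config)
    print(f"pipeline outputs under {config.output_dir}")
    somatic = out["variants"][out["variants"]["status"] == "somatic"]
    print(f"baseline somatic calls: {somatic.groupby('patient_id').size().to_dict()}")
    emr = out["quant"][out["quant"]["timepoint"] == "emr_call"]
    print("EMR calls:", dict(zip(emr["patient_id"], emr["detected"])))
    print("MRD calls:", dict(zip(out["mrd"]["patient_id"], out["mrd"]["status"])))
    seg = out["cnv_segments"]
    print("non-neutral arms:", seg[seg["call"] != "neutral"]["arm"].tolist())
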