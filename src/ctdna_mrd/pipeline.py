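"""End-to-end orchestration: fixtures, configuration and the full pipeline run.

`make_fixtures` simulates a small but complete study — four read-level
patients across four timepoints, a spike-in dilution series, a CNV sample
with panel-of-normals sidecars, and a 17-patient clinical cohort whose
EMR/response structure mirrors the modelled study design (8 EMR patients
all reaching CMR; of 9 without EMR: 1 CMR, 2 PR, 1 early death, 4
progressions, 1 unassessed).

`run_pipeline` consumes those files (or equally shaped real exports):
SAM reads -> UMI consensus -> pileup -> tumour/normal variant calls ->
tracked genotyping and phased pairs -> burden / EMR / MRD -> CNV + identity
QC -> outcome statistics, writing one TSV per stage plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import (
    compute_log2_ratios,
    genotype_concordance,
    reference_profile,
    segment_and_call,
)
from .consensus import consensus_collapse, estimate_background_error
from .outcomes import read_cohort_csv, stratify_and_report
from .panel import PanelDesign, build_panel
from .quantify import call_mrd, classify_emr, sample_quant
from .reads import read_sam
from .simulate import (
    CnvSegment,
    SimConfig,
    SomaticVariant,
    TruthSet,
    draw_genotypes,
    simulate_cnv_sample,
    simulate_sample,
    substream,
)
from .variants import (
    GenotypeTable,
    build_pileup,
    call_somatic,
    detect_phased_pairs,
    genotype_tracked,
)
from .vcfio import (
    read_backbone_counts,
    read_sample_sheet,
    write_backbone_counts,
    write_germline_vcf,
    write_sample_sheet,
)

FLANK_OFFSETS = (20, 70, 120, 220, 270)  # background positions per 300 bp target


@dataclass
class RunConfig:
    """One-file configuration for a pipeline run (YAML round-trip)."""

    input_dir: str
    output_dir: str
    seed: int = 0
    panel_seed: int = 0
    # consensus
    min_family: int = 3
    majority_frac: float = 2.0 / 3.0
    umi_tolerance: int = 0
    # calling
    alpha: float = 0.05
    min_alt_molecules: int = 2
    germline_threshold: float = 0.20
    # quantification
    pg_per_hge: float = 3.3
    floor_hge: float = 1.0
    emr_threshold_log10: float = 2.0
    # MRD
    mrd_alpha: float = 0.05
    min_phased_molecules: int = 1
    mrd_min_informative: int = 1000
    # CNV
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    # reporter exclusions (likely CHIP), as "chrom:pos:alt"
    reporter_exclude: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.majority_frac <= 1:
            raise ValueError("majority_frac outside (0, 1]")
        if self.min_family < 1 or self.min_alt_molecules < 1:
            raise ValueError("count thresholds must be >= 1")
        if not 0 < self.alpha < 1 or not 0 < self.mrd_alpha < 1:
            raise ValueError("alpha outside (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: EOT response structure of the 17-patient fixture cohort
FIXTURE_RESPONSES = ["CMR"] * 8 + ["CMR", "PR", "PR", "PD/ED", "PD/ED", "PD/ED", "PD/ED", "PD/ED", "NA"]
FIXTURE_EMR = [True] * 8 + [False] * 9

#: cohort rows simulated at read level: two EMR patients, the MRD-positive
#: non-EMR CMR patient, and one progressing non-EMR patient
READ_PATIENT_ROWS = (0, 1, 8, 9)
FIXTURE_TIMEPOINTS = [("baseline", 0), ("early", 10), ("eot", 120), ("followup", 270)]


def _fixture_cohort(seed: int) -> pd.DataFrame:
    """Deterministic 17-patient cohort with the designed EMR/response counts."""
    rng = substream(seed, "fixture-cohort")
    rows = []
    for i, (emr, resp) in enumerate(zip(FIXTURE_EMR, FIXTURE_RESPONSES)):
        if emr:
            pfs, ev = 50.0 - i, False  # no progressions among EMR patients
        elif resp in ("PD/ED",):
            pfs, ev = float(rng.uniform(2.0, 9.0)), True
        elif resp == "PR":
            pfs, ev = float(rng.uniform(10.0, 20.0)), True
        else:
            pfs, ev = 40.0, False
        os_t = min(pfs + float(rng.uniform(3.0, 12.0)), 50.0) if ev else 50.0
        base = float(10 ** rng.normal(2.725, 0.644))
        rows.append(
            {
                "patient_id": f"P{i + 1:02d}",
                "emr": emr,
                "mrd_status": "positive" if i == 8 else "negative",
                "eot_response": resp,
                "pfs_months": round(pfs, 3),
                "pfs_event": ev,
                "os_months": round(os_t, 3),
                "os_event": bool(ev and rng.random() < 0.7),
                "baseline_hge_ml": round(base, 2),
                "ldh_uln": round(max(0.3, 0.9 * (np.log10(base) - 1.2) + rng.normal(0, 0.25)), 3),
                "r_ipi": "poor" if rng.random() < 0.65 else "good",
            }
        )
    return pd.DataFrame(rows)


def _fixture_truth(panel: PanelDesign, seed: int, patient_idx: int,
                   targets) -> TruthSet:
    """Plant ~6 somatic variants (incl. one cis pair) on the read targets."""
    rng = substream(seed, "fixture-truth", patient_idx)
    variants: list[SomaticVariant] = []
    pairs = []
    for ti, t in enumerate(targets):
        centre = t.start + t.length // 2  # 1-based-ish midpoint
        for k in range(1 + (ti % 2)):
            pos = centre + k * 30 + int(rng.integers(-5, 6))
            ref = panel.ref_base(t.chrom, pos)
            alt = (ref + 1 + int(rng.integers(0, 3))) % 4
            variants.append(SomaticVariant(t.chrom, pos, ref, alt, vaf=0.40))
        if ti == 0:
            # cis pair 40 bp apart on the first target
            p1, p2 = centre - 60, centre - 20
            for p in (p1, p2):
                ref = panel.ref_base(t.chrom, p)
                variants.append(
                    SomaticVariant(t.chrom, p, ref, (ref + 1) % 4, vaf=0.40)
                )
            pairs.append((len(variants) - 2, len(variants) - 1, 1.0))
    geno = {
        f"P{patient_idx + 1:02d}": draw_genotypes(panel, substream(seed, "fixture-geno", patient_idx))
    }
    return TruthSet(somatic_variants=variants, phased_pairs=pairs,
                    germline_genotypes=geno)


def make_fixtures(seed: int, out_dir, n_molecules: int = 150) -> Path:
    """Generate the bundled simulated study under ``out_dir``.

    Returns the directory path.  Regeneration with the same seed is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = build_panel(seed=0)
    read_targets = panel.targets[:6]

    cohort = _fixture_cohort(seed)
    cohort.to_csv(out / "cohort.csv", index=False)
    panel.write_targets_bed(out / "targets.bed")
    panel.write_backbone_bed(out / "backbone.bed")

    # tumour-fraction trajectories by EMR status (EMR = complete early clearance)
    tf = {
        True: {"baseline": 0.25, "early": 0.0, "eot": 0.0, "followup": 0.0},
        False: {"baseline": 0.25, "early": 0.08, "eot": 0.02, "followup": 0.05},
    }
    sheet_rows = []
    for pi in READ_PATIENT_ROWS:
        pid = f"P{pi + 1:02d}"
        emr = bool(cohort.loc[pi, "emr"])
        truth = _fixture_truth(panel, seed, pi, read_targets)
        geno = truth.germline_genotypes[pid]
        write_germline_vcf(out / f"{pid}.germline.vcf", panel, geno, sample=pid)
        cfg = SimConfig(panel=panel, seed=seed, n_molecules=n_molecules)
        for tp, day in FIXTURE_TIMEPOINTS:
            rng = substream(seed, "fixture-reads", pi, tp)
            batch, struth = simulate_sample(
                cfg, truth, tf[emr][tp], individual=pid, rng=rng, targets=read_targets
            )
            reads_path = out / f"{pid}.{tp}.sam"
            batch.write_sam(reads_path)
            struth.write(out / f"{pid}.{tp}.truth")
            cf = {"baseline": 25.0, "early": 12.0, "eot": 6.0, "followup": 5.0}[tp]
            sheet_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "day": day,
                    "cfdna_ng_per_ml": cf,
                    "reads_path": reads_path.name,
                }
            )
    write_sample_sheet(out / "samples.csv", sheet_rows)

    # CNV sample (17p one-copy loss at tumour fraction 0.6) + 3 normals
    cnv_cfg = SimConfig(panel=panel, seed=seed)
    arm = panel.arms[(panel.arms.chrom == "chr17") & (panel.arms.arm == "17p")].iloc[0]
    segs = [CnvSegment("chr17", int(arm["start"]) + 1, int(arm["end"]), copies=1)]
    geno_p1 = _fixture_truth(panel, seed, 0, read_targets).germline_genotypes["P01"]
    cnv_tab = simulate_cnv_sample(
        cnv_cfg, segs, 0.6, geno_p1, rng=substream(seed, "fixture-cnv")
    )
    write_backbone_counts(out / "P01.cnv_backbone.tsv", cnv_tab)
    for k in range(3):
        g = draw_genotypes(panel, substream(seed, "fixture-normal", k))
        tab = simulate_cnv_sample(
            cnv_cfg, [], 0.0, g, rng=substream(seed, "fixture-normal-counts", k)
        )
        write_backbone_counts(out / f"normal{k + 1}.backbone.tsv", tab)

    RunConfig(
        input_dir=str(out), output_dir=str(out / "results"), seed=seed,
        mrd_min_informative=500,  # desk-scale fixture depth
    ).to_yaml(out / "config.yaml")
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a fixture-shaped input directory.

    Returns a dict of output DataFrames; the same tables are written as TSV
    under ``config.output_dir`` together with a run manifest.  Partial
    outputs are removed if a stage fails.
    """
    ind = Path(config.input_dir)
    outd = Path(config.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline_inner(config, ind, outd, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_pipeline_inner(config: RunConfig, ind: Path, outd: Path,
                        written: list[Path]) -> dict:
    panel = build_panel(seed=config.panel_seed)
    sheet = read_sample_sheet(_require(ind / "samples.csv"))
    cohort = read_cohort_csv(_require(ind / "cohort.csv"))
    read_targets = panel.targets[:6]
    exclude = set(config.reporter_exclude)

    flank_sites = [
        (t.chrom, t.start + off) for t in read_targets for off in FLANK_OFFSETS
    ]

    quant_rows, mrd_rows, variant_rows, ribbon_rows = [], [], [], []
    comut: dict[tuple[str, str], int] = {}
    per_sample_logs = []

    for pid, group in sheet.groupby("patient_id", sort=True):
        germline = GenotypeTable.from_vcf(_require(ind / f"{pid}.germline.vcf"), panel)
        group = group.set_index("timepoint")
        tracked = None
        phased_pairs = []
        quants = {}
        for tp, _day in FIXTURE_TIMEPOINTS:
            if tp not in group.index:
                continue
            row = group.loc[tp]
            batch = read_sam(_require(ind / row["reads_path"]), panel)
            cons = consensus_collapse(
                batch,
                min_family=config.min_family,
                majority_frac=config.majority_frac,
                umi_tolerance=config.umi_tolerance,
            )
            pileup = build_pileup(cons, read_targets)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                error_model = estimate_background_error(
                    cons, flank_sites, germline.variant_loci()
                )
            per_sample_logs.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "reads_in": batch.n_reads,
                    "consensus_molecules": cons.n_molecules,
                    "background_rate": error_model.rate,
                }
            )
            if tp == "baseline":
                calls = call_somatic(
                    pileup,
                    germline,
                    error_model,
                    alpha=config.alpha,
                    min_alt_molecules=config.min_alt_molecules,
                    germline_threshold=config.germline_threshold,
                )
                somatic = [c for c in calls if c.status == "somatic"]
                tracked = [
                    c.key for c in somatic
                    if f"{c.chrom}:{c.pos}:{c.alt}" not in exclude
                ]
                phased_pairs = detect_phased_pairs(cons, somatic)
                for c in calls:
                    variant_rows.append(
                        {
                            "patient_id": pid,
                            "chrom": c.chrom, "pos": c.pos, "ref": c.ref,
                            "alt": c.alt, "alt_molecules": c.alt_molecules,
                            "informative": c.informative_molecules,
                            "vaf": c.vaf, "p_value": c.p_value, "status": c.status,
                        }
                    )
                for c in somatic:
                    gene = next(
                        (t.name for t in read_targets
                         if t.chrom == c.chrom and t.start < c.pos <= t.end),
                        "",
                    )
                    if gene:
                        comut[(gene, pid)] = comut.get((gene, pid), 0) + 1
            if not tracked:
                continue
            geno = genotype_tracked(pileup, tracked)
            for _, g in geno.iterrows():
                ribbon_rows.append(
                    {
                        "patient_id": pid, "timepoint": tp,
                        "chrom": g["chrom"], "pos": g["pos"], "alt": g["alt"],
                        "vaf": g["vaf"],
                    }
                )
            sq = sample_quant(
                pid, tp, int(row["day"]), geno,
                float(row["cfdna_ng_per_ml"]), config.pg_per_hge,
            )
            quants[tp] = sq
            quant_rows.append(
                {
                    "patient_id": pid, "timepoint": tp, "day": int(row["day"]),
                    "cfdna_ng_per_ml": sq.cfdna_ng_per_ml,
                    "mean_vaf": sq.mean_vaf,
                    "burden_hge_ml": sq.burden_hge_ml,
                    "detected": sq.detected,
                }
            )
            if tp == "followup":
                pair_support = 0
                if phased_pairs:
                    tracked_pairs = [
                        (p.chrom, p.pos_a, "", p.alt_a) for p in phased_pairs
                    ] + [(p.chrom, p.pos_b, "", p.alt_b) for p in phased_pairs]
                    redetected = detect_phased_pairs(cons, tracked_pairs)
                    pair_support = sum(p.support for p in redetected)
                mrd = call_mrd(
                    pid, tp, geno, pair_support, error_model,
                    alpha=config.mrd_alpha,
                    min_phased_molecules=config.min_phased_molecules,
                    min_informative=config.mrd_min_informative,
                )
                mrd_rows.append(
                    {
                        "patient_id": pid, "timepoint": tp, "status": mrd.status,
                        "p_value": mrd.p_value, "alt_molecules": mrd.alt_molecules,
                        "informative": mrd.informative_molecules,
                        "reporters_with_signal": mrd.reporters_with_signal,
                        "phased_molecules": mrd.phased_molecules,
                        "route": mrd.route,
                    }
                )
        # EMR classification
        if tracked and "baseline" in quants and "early" in quants:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emr, delta = classify_emr(
                    quants["baseline"], quants["early"],
                    floor_hge=config.floor_hge,
                    threshold_log10=config.emr_threshold_log10,
                )
            quant_rows.append(
                {
                    "patient_id": pid, "timepoint": "emr_call", "day": -1,
                    "cfdna_ng_per_ml": np.nan, "mean_vaf": np.nan,
                    "burden_hge_ml": np.nan,
                    "detected": bool(emr) if emr is not None else None,
                }
            )

    # CNV + LOH on the dedicated backbone count sample
    normals = [read_backbone_counts(_require(ind / f"normal{k + 1}.backbone.tsv"))
               for k in range(3)]
    ref = reference_profile(normals)
    cnv_tab = read_backbone_counts(_require(ind / "P01.cnv_backbone.tsv"))
    profile = compute_log2_ratios(cnv_tab, ref, panel)
    het = {
        (r["chrom"], r["pos"])
        for _, r in cnv_tab.iterrows()
        if r.get("genotype", 0) == 1
    }
    seg_calls = segment_and_call(
        profile, het,
        gain_threshold=config.gain_threshold,
        loss_threshold=config.loss_threshold,
    )
    cnv_df = pd.DataFrame(
        [
            {
                "arm": s.arm, "chrom": s.chrom, "n_loci": s.n_loci,
                "median_log2": s.median_log2, "call": s.call,
                "p_value": s.p_value, "loh": s.loh, "baf_deviation": s.baf_deviation,
            }
            for s in seg_calls
        ]
    )

    # identity QC: CNV sample vs the panel-of-normals samples
    qc_rows = []
    for k, tab in enumerate(normals):
        res = genotype_concordance(cnv_tab, tab)
        qc_rows.append(
            {
                "sample_a": "P01.cnv", "sample_b": f"normal{k + 1}",
                "concordance": res["concordance"], "n_loci": res["n_loci"],
                "mislabelled": res["mislabelled"],
            }
        )
    self_res = genotype_concordance(cnv_tab, cnv_tab)
    qc_rows.append(
        {
            "sample_a": "P01.cnv", "sample_b": "P01.cnv",
            "concordance": self_res["concordance"], "n_loci": self_res["n_loci"],
            "mislabelled": self_res["mislabelled"],
        }
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = stratify_and_report(cohort, "emr")

    outputs = {
        "variants": pd.DataFrame(variant_rows),
        "quant": pd.DataFrame(quant_rows),
        "mrd": pd.DataFrame(mrd_rows),
        "ribbon": pd.DataFrame(ribbon_rows),
        "comutation": pd.DataFrame(
            [{"gene": g, "patient_id": p, "n_variants": n} for (g, p), n in sorted(comut.items())]
        ),
        "cnv_segments": cnv_df,
        "identity_qc": pd.DataFrame(qc_rows),
        "stage_log": pd.DataFrame(per_sample_logs),
        "outcomes": pd.DataFrame(
            [
                {
                    "stratifier": "emr",
                    "cmr_rate_emr": bundle["cmr_rate"][0],
                    "cmr_rate_no_emr": bundle["cmr_rate"][1],
                    "fisher_p": bundle["fisher_p"],
                    "logrank_p": bundle["logrank_p"],
                    "hazard_ratio": bundle["hazard_ratio"],
                    "hr_ci_low": bundle["hazard_ratio_ci"][0],
                    "hr_ci_high": bundle["hazard_ratio_ci"][1],
                    "pfs24_emr": bundle["pfs_24m"][0],
                    "pfs24_no_emr": bundle["pfs_24m"][1],
                    "median_followup": bundle["median_followup"],
                }
            ]
        ),
    }
    for name, df in outputs.items():
        path = outd / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: v for k, v in asdict(config).items()
                 if k not in ("input_dir", "output_dir")},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    mpath = outd / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(mpath)
    outputs["bundle"] = bundle
    return outputs
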