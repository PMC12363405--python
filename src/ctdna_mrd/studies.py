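"""Desk-scale analytical-validation studies of the assay model.

Each function runs one self-contained experiment end to end through the
library — simulate, collapse, call, measure — and returns its summary.
They are the computational core behind the numbered analysis scripts and
the reproducibility harness; sizes default to the study conditions
(101 spike-in SNP sites at ~5000 consensus molecules each, per-base error
0.003, UMI family minimum 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import compute_log2_ratios, genotype_concordance, reference_profile, segment_and_call
from .consensus import consensus_collapse, estimate_background_error
from .outcomes import fisher_exact_2x2, logrank_test, mh_hazard_ratio
from .panel import BASES, PanelDesign, build_panel
from .quantify import LodReport, run_dilution_series
from .simulate import (
    ClinicalSimSpec,
    CnvSegment,
    SimConfig,
    SomaticVariant,
    TruthSet,
    draw_genotypes,
    molecules_for_consensus_depth,
    position_coverage_fraction,
    simulate_cnv_sample,
    simulate_cohort,
    simulate_sample,
    substream,
)
from .variants import build_pileup, detect_phased_pairs, genotype_tracked


def dilution_study(
    seed: int,
    mix_fraction: float = 0.002,
    replicates: int = 10,
    n_sites: int = 101,
    depth: int = 5000,
    panel: PanelDesign | None = None,
) -> LodReport:
    """Spike-in sensitivity at a given admixture fraction.

    Two simulated individuals are mixed at ``mix_fraction`` over
    ``n_sites`` discordant backbone SNPs at ~``depth`` consensus molecules
    per site, and each site is tested against the run's own flanking-site
    background (Bonferroni over sites).
    """
    panel = panel if panel is not None else build_panel(seed=0)
    cfg = SimConfig(panel=panel, seed=seed)
    cfg.n_molecules = molecules_for_consensus_depth(cfg, depth)
    return run_dilution_series(
        [mix_fraction], replicates, cfg, n_sites=n_sites, seed=seed
    )


def error_suppression_study(
    seed: int,
    per_base_error: float = 0.003,
    n_targets: int = 10,
    n_molecules: int = 2000,
    panel: PanelDesign | None = None,
) -> dict:
    """Raw vs post-consensus background error on a variant-free sample.

    The raw rate is the per-base mismatch rate of the emitted reads; the
    post-consensus rate pools most-frequent-alt molecule calls over fixed
    variant-free positions spread across the targets (UMI family minimum 3,
    2/3 majority).
    """
    panel = panel if panel is not None else build_panel(seed=0)
    targets = panel.targets[:n_targets]
    cfg = SimConfig(panel=panel, seed=seed, n_molecules=n_molecules,
                    per_base_error=per_base_error)
    batch, truth = simulate_sample(
        cfg, TruthSet(), 0.0, rng=substream(seed, "errstudy"), targets=targets
    )
    cons = consensus_collapse(batch)
    offsets = (20, 45, 70, 95, 120, 180, 205, 230, 255, 280)
    sites = [(t.chrom, t.start + o) for t in targets for o in offsets]
    em = estimate_background_error(cons, sites)
    raw = truth.raw_error_rate
    return {
        "raw_error_rate": raw,
        "post_consensus_rate": em.rate,
        "suppression_fold": raw / em.rate if em.rate > 0 else float("inf"),
        "alt_molecules": em.alt_molecules,
        "molecule_sites": em.total_molecules,
    }


def vaf_recovery_study(
    seed: int,
    vafs: tuple[float, ...] = (0.10, 0.01, 0.002),
    replicates: int = 100,
    depth: int = 5000,
    panel: PanelDesign | None = None,
) -> pd.DataFrame:
    """Exact-binomial CI coverage of tracked-variant VAF estimates.

    One variant per target at the target midpoint, simulated at tumour
    fraction 1 so the planted VAF is the molecular truth; each replicate
    checks whether the Clopper–Pearson 95% interval of alt/informative
    contains the planted value.
    """
    panel = panel if panel is not None else build_panel(seed=0)
    targets = panel.targets[: len(vafs)]
    variants = []
    for t, vaf in zip(targets, vafs):
        pos = t.start + t.length // 2
        ref = panel.ref_base(t.chrom, pos)
        variants.append(SomaticVariant(t.chrom, pos, ref, (ref + 1) % 4, vaf))
    truth = TruthSet(somatic_variants=variants)
    cfg = SimConfig(panel=panel, seed=seed)
    mid_cov = position_coverage_fraction(cfg, targets[0].length,
                                         targets[0].length // 2)
    cfg.n_molecules = int(np.ceil(molecules_for_consensus_depth(cfg, depth) / mid_cov))

    hits = np.zeros(len(vafs), dtype=int)
    depths = np.zeros(len(vafs))
    for rep in range(replicates):
        rng = substream(seed, "recovery", rep)
        batch, _ = simulate_sample(cfg, truth, 1.0, rng=rng, targets=targets)
        pile = build_pileup(consensus_collapse(batch), targets)
        tracked = genotype_tracked(
            pile, [(v.chrom, v.pos, BASES[v.ref], BASES[v.alt]) for v in variants]
        )
        for i, (v, row) in enumerate(zip(variants, tracked.itertuples())):
            ci = stats.binomtest(
                int(row.alt_molecules), int(row.informative_molecules)
            ).proportion_ci(0.95)
            hits[i] += ci.low <= v.vaf <= ci.high
            depths[i] += row.informative_molecules
    return pd.DataFrame(
        {
            "vaf": vafs,
            "replicates": replicates,
            "covered": hits,
            "coverage_pct": 100.0 * hits / replicates,
            "mean_informative": depths / replicates,
        }
    )


def phasing_study(
    seed: int,
    distances: tuple[int, ...] = (40, 80, 100),
    beyond: int = 102,
    vaf: float = 0.05,
    n_molecules: int = 1000,
    panel: PanelDesign | None = None,
) -> dict:
    """Recovery of planted cis pairs inside/outside the 100 bp window.

    Returns the consensus set, variant list and detected pairs so callers
    can cross-check against an exhaustive oracle, plus summary counts.
    """
    panel = panel if panel is not None else build_panel(seed=0)
    all_d = list(distances) + [beyond]
    targets = panel.targets[: len(all_d)]
    variants: list[SomaticVariant] = []
    pairs = []
    for t, d in zip(targets, all_d):
        mid = t.start + t.length // 2
        p1, p2 = mid - d // 2, mid - d // 2 + d
        for p in (p1, p2):
            ref = panel.ref_base(t.chrom, p)
            variants.append(SomaticVariant(t.chrom, p, ref, (ref + 1) % 4, vaf))
        if d <= 100:
            pairs.append((len(variants) - 2, len(variants) - 1, 1.0))
    truth = TruthSet(somatic_variants=variants, phased_pairs=pairs)
    cfg = SimConfig(panel=panel, seed=seed, n_molecules=n_molecules)
    batch, _ = simulate_sample(
        cfg, truth, 1.0, rng=substream(seed, "phasing"), targets=targets
    )
    cons = consensus_collapse(batch)
    vtuples = [(v.chrom, v.pos, BASES[v.ref], BASES[v.alt]) for v in variants]
    detected = detect_phased_pairs(cons, vtuples)
    planted = {
        (variants[i].pos, variants[j].pos) for i, j, _ in pairs
    }
    got = {(p.pos_a, p.pos_b) for p in detected}
    return {
        "consensus": cons,
        "variants": vtuples,
        "detected": detected,
        "planted_pairs": len(planted),
        "recovered_pairs": len(planted & got),
        "recovered_pct": 100.0 * len(planted & got) / len(planted),
        "beyond_window_detected": sum(
            1 for p in got if abs(p[0] - p[1]) > 100
        ),
    }


def logrank_null_study(
    seed: int,
    replicates: int = 500,
    n_per_group: int = 100,
    alpha: float = 0.05,
    censor_time: float = 30.0,
) -> dict:
    """Type-I error of the log-rank test under equal hazards.

    Exponential event times in both groups with administrative censoring at
    ``censor_time`` (trial-style follow-up, so risk sets stay informative
    across the whole observation window).
    """
    rng = substream(seed, "logrank-null")
    rejections = 0
    for _ in range(replicates):
        ta = rng.exponential(12.0, n_per_group)
        tb = rng.exponential(12.0, n_per_group)
        _, p = logrank_test(
            np.minimum(ta, censor_time), ta <= censor_time,
            np.minimum(tb, censor_time), tb <= censor_time,
        )
        rejections += p <= alpha
    rate = rejections / replicates
    return {
        "replicates": replicates,
        "rejection_rate": rate,
        "se": np.sqrt(alpha * (1 - alpha) / replicates),
    }


def hazard_ratio_recovery_study(seed: int, n_patients: int = 2000) -> dict:
    """Consistency of the MH hazard ratio on a large designed cohort."""
    spec = ClinicalSimSpec(n_patients=n_patients, hazard_emr=0.0034,
                           hazard_no_emr=0.034)
    cohort, _ = simulate_cohort(spec, seed=seed)
    g, h = cohort[cohort["emr"]], cohort[~cohort["emr"]]
    hr, ci = mh_hazard_ratio(g["pfs_months"], g["pfs_event"],
                             h["pfs_months"], h["pfs_event"])
    return {"true_hr": spec.hazard_emr / spec.hazard_no_emr,
            "estimated_hr": hr, "ci": ci}


def fisher_enumeration_check(max_n: int = 30) -> dict:
    """Compare the Fisher implementation to scipy over all tables with N <= max_n."""
    from scipy.stats import fisher_exact as scipy_fisher

    worst = 0.0
    count = 0
    for n in range(2, max_n + 1):
        for r1 in range(1, n):
            for c1 in range(1, n):
                lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                for a in range(lo, hi + 1):
                    t = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                    p_ours, _ = fisher_exact_2x2(t)
                    p_ref = scipy_fisher(t).pvalue
                    worst = max(worst, abs(p_ours - p_ref))
                    count += 1
    return {"tables": count, "max_abs_diff": worst}


def cnv_identity_study(seed: int, tumour_fraction: float = 0.6,
                       depth: float = 2000.0,
                       panel: PanelDesign | None = None) -> dict:
    """17p one-copy loss detection + LOH + identity QC on the backbone."""
    panel = panel if panel is not None else build_panel(seed=0)
    cfg = SimConfig(panel=panel, seed=seed)
    normals = []
    for k in range(3):
        g = draw_genotypes(panel, substream(seed, "cnv-normal", k))
        normals.append(
            simulate_cnv_sample(cfg, [], 0.0, g, base_depth=depth,
                                rng=substream(seed, "cnv-normal-counts", k))
        )
    ref = reference_profile(normals)
    arm = panel.arms[(panel.arms.chrom == "chr17") & (panel.arms.arm == "17p")].iloc[0]
    seg = CnvSegment("chr17", int(arm["start"]) + 1, int(arm["end"]), 1)
    geno = draw_genotypes(panel, substream(seed, "cnv-tumour"))
    tumour = simulate_cnv_sample(cfg, [seg], tumour_fraction, geno,
                                 base_depth=depth,
                                 rng=substream(seed, "cnv-tumour-counts"))
    prof = compute_log2_ratios(tumour, ref, panel)
    het = {(r["chrom"], r["pos"]) for _, r in tumour.iterrows()
           if r["genotype"] == 1}
    calls = {c.arm: c for c in segment_and_call(prof, het)}
    unrelated = genotype_concordance(tumour, normals[0])
    return {
        "calls": calls,
        "log2_17p": calls["17p"].median_log2,
        "expected_log2": float(np.log2(1 - tumour_fraction / 2)),
        "loh_17p": calls["17p"].loh,
        "neutral_arms_clean": all(
            c.call == "neutral" for a, c in calls.items() if a != "17p"
        ),
        "unrelated_concordance": unrelated["concordance"],
        "unrelated_flagged": bool(unrelated["mislabelled"]),
    }
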