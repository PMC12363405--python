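"""Copy-number, LOH and sample-identity analysis over the SNP backbone.

The assay carries ~1000 common SNPs spread across the genome.  Depth at
those loci, normalised per sample and against a panel-of-normals reference
profile, yields a log2 copy-ratio per locus; B-allele fractions at
germline-heterozygous loci reveal allelic imbalance (LOH).  Calls are made
at chromosome-arm resolution: the recurrent lesions in aggressive B-cell
lymphoma (17p loss, 12q gain, 16p loss) are arm/segment scale, so a median
log2 plus a sign test across the arm's loci is a robust caller without
segmentation machinery.  The same backbone genotypes double as a sample
fingerprint for detecting mislabelled specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDesign

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
MIN_LOCI = 5
LOH_DEVIATION = 0.15
CONCORDANCE_FLAG = 0.80


@dataclass
class BackboneProfile:
    """Per-locus backbone measurements for one sample.

    ``table`` columns: chrom, pos, arm, depth, ref_count, alt_count, baf,
    norm_depth (library-size normalised), log2_ratio (vs reference profile;
    NaN where masked).
    """

    table: pd.DataFrame

    def arm_loci(self, arm: str) -> pd.DataFrame:
        return self.table[self.table["arm"] == arm]


@dataclass(frozen=True)
class SegmentCall:
    """Arm-level copy-number call."""

    arm: str
    chrom: str
    n_loci: int
    median_log2: float
    call: str  # gain | neutral | loss | no-call
    p_value: float
    loh: str  # yes | no | unevaluable
    baf_deviation: float


def expected_log2(copies: int, tumour_fraction: float) -> float:
    """Expected log2 ratio for a clonal segment at a given tumour fraction."""
    return float(np.log2((1 - tumour_fraction) + tumour_fraction * copies / 2.0))


def reference_profile(normal_tables: list[pd.DataFrame]) -> pd.Series:
    """Median library-size-normalised depth per locus from >= 3 normals."""
    if len(normal_tables) < 3:
        raise ValueError("reference profile requires >= 3 normal samples")
    norm = []
    for t in normal_tables:
        med = t["depth"].median()
        if med <= 0:
            raise ValueError("normal sample with zero median depth")
        norm.append(t["depth"].to_numpy() / med)
    return pd.Series(np.median(np.vstack(norm), axis=0))


def compute_log2_ratios(
    sample: pd.DataFrame,
    reference: pd.Series,
    panel: PanelDesign,
    min_ref_depth: float = 0.1,
) -> BackboneProfile:
    """Per-locus log2 ratio of normalised sample depth over the reference.

    ``sample`` is a backbone count table (chrom, pos, depth, ref_count,
    alt_count) aligned to ``panel.backbone``; loci whose reference profile
    falls below ``min_ref_depth`` (relative units) are masked.
    """
    if len(sample) != len(reference):
        raise ValueError("sample and reference profiles are not aligned")
    med = sample["depth"].median()
    if med <= 0:
        raise ValueError("sample has zero median backbone depth")
    norm_depth = sample["depth"].to_numpy() / med
    ref = reference.to_numpy()
    masked = ref < min_ref_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(norm_depth / ref)
    log2r[masked | ~np.isfinite(log2r)] = np.nan
    depth = sample["depth"].to_numpy()
    alt = sample["alt_count"].to_numpy()
    baf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    arms = [panel.arm_of(c, p) for c, p in zip(sample["chrom"], sample["pos"])]
    table = sample.assign(arm=arms, norm_depth=norm_depth, baf=baf, log2_ratio=log2r)
    return BackboneProfile(table=table)


def _loh_flag(
    arm_table: pd.DataFrame, het_loci: set[tuple[str, int]], min_het: int = MIN_LOCI
) -> tuple[str, float]:
    het = arm_table[
        [((c, p) in het_loci) for c, p in zip(arm_table["chrom"], arm_table["pos"])]
    ]
    het = het[het["depth"] > 0]
    if len(het) < min_het:
        return "unevaluable", float("nan")
    dev = float(np.mean(np.abs(het["baf"] - 0.5)))
    return ("yes" if dev >= LOH_DEVIATION else "no"), dev


def segment_and_call(
    profile: BackboneProfile,
    het_loci: set[tuple[str, int]] | None = None,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_loci: int = MIN_LOCI,
    alpha: float = 0.05,
) -> list[SegmentCall]:
    """Arm-level gain/loss calls with sign-test confirmation plus LOH flags.

    An arm is called when its median log2 ratio exceeds the threshold and a
    two-sided sign test across the arm's loci rejects symmetry around zero
    at ``alpha``; arms with fewer than ``min_loci`` usable loci yield
    no-call.  LOH is evaluated from B-allele deviation at germline-het loci
    when provided.
    """
    het_loci = het_loci or set()
    calls = []
    for arm in profile.table["arm"].unique():
        if not arm:
            continue
        sub = profile.arm_loci(arm)
        vals = sub["log2_ratio"].dropna().to_numpy()
        loh, dev = _loh_flag(sub, het_loci) if het_loci else ("unevaluable", float("nan"))
        chrom = sub["chrom"].iloc[0]
        if len(vals) < min_loci:
            calls.append(
                SegmentCall(arm, chrom, len(vals), float(np.median(vals)) if len(vals) else float("nan"),
                            "no-call", float("nan"), loh, dev)
            )
            continue
        med = float(np.median(vals))
        nz = vals[vals != 0]
        n_pos = int((nz > 0).sum())
        p = float(stats.binomtest(n_pos, len(nz), 0.5).pvalue) if len(nz) else 1.0
        if med >= gain_threshold and p <= alpha:
            call = "gain"
        elif med <= loss_threshold and p <= alpha:
            call = "loss"
        else:
            call = "neutral"
        calls.append(SegmentCall(arm, chrom, len(vals), med, call, p, loh, dev))
    return calls


def detect_loh(
    profile: BackboneProfile, het_loci: set[tuple[str, int]], min_het: int = MIN_LOCI
) -> dict[str, tuple[str, float]]:
    """Per-arm LOH flags from B-allele deviation at germline-het loci."""
    out = {}
    for arm in profile.table["arm"].unique():
        if arm:
            out[arm] = _loh_flag(profile.arm_loci(arm), het_loci, min_het)
    return out


# ---------------------------------------------------------------------------
# identity QC
# ---------------------------------------------------------------------------


def genotype_calls(table: pd.DataFrame, min_depth: int = 20) -> np.ndarray:
    """Genotype backbone loci by VAF bins (<0.1 / 0.1-0.9 / >0.9).

    Returns 0/1/2 alt copies, -1 where depth is below ``min_depth``.
    """
    depth = table["depth"].to_numpy()
    vaf = np.where(depth > 0, table["alt_count"].to_numpy() / np.maximum(depth, 1), 0.0)
    calls = np.where(vaf > 0.9, 2, np.where(vaf >= 0.1, 1, 0))
    return np.where(depth >= min_depth, calls, -1)


def genotype_concordance(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame, min_depth: int = 20,
    min_loci: int = 100, flag_below: float = CONCORDANCE_FLAG,
) -> dict:
    """Backbone genotype concordance between two samples.

    Concordance is the fraction of matching genotype calls over loci called
    in both samples; values below ``flag_below`` raise the mislabel flag
    (unrelated individuals sharing a 0.5-AF backbone agree only ~37.5% of
    the time under Hardy–Weinberg).  Fewer than ``min_loci`` co-called loci
    is unevaluable.
    """
    if len(sample_a) != len(sample_b):
        raise ValueError("samples genotyped on different backbones")
    ga = genotype_calls(sample_a, min_depth)
    gb = genotype_calls(sample_b, min_depth)
    both = (ga >= 0) & (gb >= 0)
    n = int(both.sum())
    if n < min_loci:
        return {"concordance": float("nan"), "n_loci": n,
                "mislabelled": None, "evaluable": False}
    conc = float((ga[both] == gb[both]).mean())
    return {"concordance": conc, "n_loci": n,
            "mislabelled": conc < flag_below, "evaluable": True}
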