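"""ctDNA burden quantification, EMR classification, MRD calling and LOD analysis.

Burden follows the CAPP-Seq convention: plasma cfDNA concentration is
converted to haploid genome equivalents per millilitre (3.3 pg per haploid
genome) and scaled by the mean VAF across tracked tumour reporters:

    hGE/mL = (cfDNA ng/mL x 1000 / 3.3 pg) x mean reporter VAF

Early molecular response (EMR) is a >= 2 log10 reduction in burden between
the pre-treatment sample and an early on-treatment draw during cycle 1.
MRD calling aggregates tracked reporters into one binomial test against the
assay background, with an alternative phased-variant route: a single
consensus molecule carrying both members of a known cis pair is far beyond
what independent background errors produce, so it can establish positivity
on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ErrorModel, consensus_collapse, estimate_background_error
from .simulate import SimConfig, simulate_dilution, draw_genotypes, substream

PG_PER_HGE = 3.3  # picograms of DNA per haploid genome equivalent
EMR_THRESHOLD_LOG10 = 2.0
EARLY_WINDOW_DAYS = (7, 22)


def quantify_burden(
    mean_vaf: float, cfdna_ng_per_ml: float, pg_per_hge: float = PG_PER_HGE
) -> float:
    """ctDNA burden in hGE/mL from mean reporter VAF and cfDNA concentration."""
    if mean_vaf < 0 or cfdna_ng_per_ml < 0 or pg_per_hge <= 0:
        raise ValueError("inputs must be non-negative (pg_per_hge positive)")
    return cfdna_ng_per_ml * 1000.0 / pg_per_hge * mean_vaf


@dataclass
class SampleQuant:
    """Per-timepoint ctDNA quantification."""

    patient_id: str
    timepoint: str
    day: int
    cfdna_ng_per_ml: float
    mean_vaf: float
    burden_hge_ml: float
    detected: bool
    log10_burden: float = field(init=False)

    def __post_init__(self):
        if self.burden_hge_ml < 0:
            raise ValueError("burden must be >= 0")
        self.log10_burden = (
            float(np.log10(self.burden_hge_ml)) if self.burden_hge_ml > 0 else -np.inf
        )


def sample_quant(
    patient_id: str,
    timepoint: str,
    day: int,
    tracked: pd.DataFrame,
    cfdna_ng_per_ml: float,
    pg_per_hge: float = PG_PER_HGE,
) -> SampleQuant:
    """Summarise tracked-reporter genotyping into a burden estimate.

    The mean VAF is taken over reporters with non-missing genotyping;
    ``detected`` requires at least one alt molecule among them.
    """
    usable = tracked[~tracked["missing"]]
    mean_vaf = float(usable["vaf"].mean()) if len(usable) else 0.0
    detected = bool((usable["alt_molecules"] > 0).any()) if len(usable) else False
    return SampleQuant(
        patient_id=patient_id,
        timepoint=timepoint,
        day=day,
        cfdna_ng_per_ml=cfdna_ng_per_ml,
        mean_vaf=mean_vaf,
        burden_hge_ml=quantify_burden(mean_vaf, cfdna_ng_per_ml, pg_per_hge),
        detected=detected,
    )


def classify_emr(
    baseline: SampleQuant,
    early: SampleQuant,
    floor_hge: float = 1.0,
    threshold_log10: float = EMR_THRESHOLD_LOG10,
) -> tuple[bool | None, float]:
    """Early molecular response: >= 2 log10 drop from baseline (inclusive).

    Undetected early samples are imputed at ``floor_hge`` before the log
    ratio.  Returns (EMR flag, delta log10); the flag is None (unevaluable)
    when the baseline itself is undetected.  A warning is issued when the
    early draw lies outside the observed day-7..22 cycle-1 window.
    """
    if not baseline.detected or baseline.burden_hge_ml <= 0:
        return None, float("nan")
    if not EARLY_WINDOW_DAYS[0] <= early.day <= EARLY_WINDOW_DAYS[1]:
        warnings.warn(
            f"early sample day {early.day} outside the cycle-1 window "
            f"{EARLY_WINDOW_DAYS[0]}-{EARLY_WINDOW_DAYS[1]}"
        )
    early_burden = early.burden_hge_ml if early.detected and early.burden_hge_ml > 0 else floor_hge
    delta = float(np.log10(baseline.burden_hge_ml) - np.log10(early_burden))
    return delta >= threshold_log10, delta


@dataclass
class MrdResult:
    """MRD classification for one monitoring timepoint."""

    patient_id: str
    timepoint: str
    status: str  # positive | negative | unevaluable
    p_value: float
    alt_molecules: int
    informative_molecules: int
    reporters_with_signal: int
    phased_molecules: int
    route: str  # aggregate | phased | both | none


def call_mrd(
    patient_id: str,
    timepoint: str,
    tracked: pd.DataFrame,
    phased_molecules: int,
    error_model: ErrorModel,
    alpha: float = 0.05,
    min_phased_molecules: int = 1,
    min_informative: int = 1000,
) -> MrdResult:
    """Classify MRD from tracked reporters and phased-pair evidence.

    Positive if either (a) the aggregate one-sided binomial test of summed
    alt vs summed informative molecules against the background rate gives
    p <= alpha with >= 2 distinct reporters showing signal, or (b) at least
    ``min_phased_molecules`` consensus molecules carry both members of a
    known phased pair.  Unevaluable when informative molecules across
    reporters fall below ``min_informative``.
    """
    usable = tracked[~tracked["missing"]] if len(tracked) else tracked
    total_inf = int(usable["informative_molecules"].sum()) if len(usable) else 0
    total_alt = int(usable["alt_molecules"].sum()) if len(usable) else 0
    n_signal = int((usable["alt_molecules"] > 0).sum()) if len(usable) else 0

    if len(usable) == 0 or total_inf < min_informative:
        return MrdResult(
            patient_id, timepoint, "unevaluable", float("nan"),
            total_alt, total_inf, n_signal, phased_molecules, "none",
        )

    p = float(stats.binom.sf(total_alt - 1, total_inf, error_model.rate)) if total_alt else 1.0
    via_aggregate = p <= alpha and n_signal >= 2
    via_phased = phased_molecules >= min_phased_molecules
    route = {
        (True, True): "both",
        (True, False): "aggregate",
        (False, True): "phased",
        (False, False): "none",
    }[(via_aggregate, via_phased)]
    status = "positive" if (via_aggregate or via_phased) else "negative"
    return MrdResult(
        patient_id, timepoint, status, p,
        total_alt, total_inf, n_signal, phased_molecules, route,
    )


# ---------------------------------------------------------------------------
# dilution series / limit of detection
# ---------------------------------------------------------------------------


@dataclass
class LodReport:
    """Detection table for a SNP spike-in dilution series.

    ``table`` has one row per (mix fraction, replicate): sites tested,
    sites detected, mean observed VAF at detected sites, and the background
    rate used.  ``sensitivity`` is the lowest mix fraction whose mean
    detection fraction is >= 0.95.
    """

    table: pd.DataFrame
    sensitivity: float
    background_rate: float

    def mean_detected(self, fraction: float) -> float:
        sub = self.table[self.table["mix_fraction"] == fraction]
        return float(sub["sites_detected"].mean()) if len(sub) else float("nan")


def run_dilution_series(
    mix_fractions: list[float],
    replicates: int,
    cfg: SimConfig,
    n_sites: int = 101,
    alpha: float = 0.05,
    min_alt_molecules: int = 2,
    min_family: int = 3,
    seed: int | None = None,
) -> LodReport:
    """Simulate two-individual spike-ins and score per-site detection.

    For each mix fraction and replicate a fresh admixture read set is
    simulated over ``n_sites`` discordant backbone SNPs, collapsed to
    consensus, and each site is tested against the background error rate
    estimated from the SNP-flanking positions of the same run (one-sided
    binomial, Bonferroni over the tested sites).
    """
    if list(mix_fractions) != sorted(mix_fractions, reverse=True):
        raise ValueError("mix fractions must be sorted descending")
    seed = cfg.seed if seed is None else seed
    geno_rng = substream(seed, "dilution-genotypes")
    panel = cfg.panel
    # two unrelated individuals with enough discordant sites
    for attempt in range(20):
        ga, gb = draw_genotypes(panel, geno_rng), draw_genotypes(panel, geno_rng)
        if int(((ga == 0) & (gb > 0)).sum()) >= n_sites:
            break
    else:
        raise ValueError("could not draw genotypes with enough discordant sites")

    rows = []
    bg_rates = []
    for fi, frac in enumerate(mix_fractions):
        for rep in range(replicates):
            rng = substream(seed, "dilution", fi, rep)
            batch, truth = simulate_dilution(cfg, ga, gb, frac, n_sites, rng=rng)
            cons = consensus_collapse(batch, min_family=min_family)
            sites = list(zip(truth["chrom"], truth["pos"]))
            flanks = [(c, p + d) for c, p in sites for d in (-1, 1)]
            em = estimate_background_error(cons, flanks)
            bg_rates.append(em.rate)
            counts = cons.site_counts(sites)
            alt = np.array(
                [row[truth.loc[i, "alt"]] for i, row in counts.iterrows()]
            )
            informative = counts["depth"].to_numpy() - counts["N"].to_numpy()
            pv = stats.binom.sf(alt - 1, informative, em.rate)
            detected = (alt >= min_alt_molecules) & (pv <= alpha / n_sites)
            vafs = np.where(informative > 0, alt / np.maximum(informative, 1), np.nan)
            rows.append(
                {
                    "mix_fraction": frac,
                    "replicate": rep,
                    "sites_tested": n_sites,
                    "sites_detected": int(detected.sum()),
                    "mean_detected_vaf": float(np.nanmean(np.where(detected, vafs, np.nan)))
                    if detected.any()
                    else float("nan"),
                    "mean_consensus_depth": float(informative.mean()),
                    "background_rate": em.rate,
                }
            )
    table = pd.DataFrame(rows)
    sens = float("nan")
    for frac in sorted(mix_fractions):
        sub = table[table["mix_fraction"] == frac]
        if (sub["sites_detected"] / sub["sites_tested"]).mean() >= 0.95:
            sens = frac
            break
    return LodReport(
        table=table,
        sensitivity=sens,
        background_rate=float(np.mean(bg_rates)),
    )
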