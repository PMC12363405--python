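"""Tumour/normal somatic variant analysis on consensus molecules.

Discovery is a per-position one-sided binomial test of the alt consensus
molecule count against the assay's background error rate, Bonferroni
corrected over all tested panel positions, with germline subtraction from
matched buccal genotypes.  Tracked-variant genotyping (for longitudinal
MRD monitoring) is threshold-free: counts are reported for every tracked
reporter whether or not they reach discovery significance.  Phased-pair
detection looks for somatic variants within 100 bp observed in cis on the
same consensus molecule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .consensus import ConsensusSet
from .panel import BASES, PanelDesign, TargetInterval

GERMLINE_VAF_THRESHOLD = 0.20


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass
class Pileup:
    """Per-position consensus molecule counts over target regions.

    ``counts`` holds one (L, 5) matrix per region (columns A,C,G,T,N);
    the sum across columns at a position equals the molecules covering it,
    and ``informative`` excludes the N (masked) calls.
    """

    panel: PanelDesign
    regions: list[tuple[str, int, int]]  # (chrom, start, end) 1-based inclusive
    counts: list[np.ndarray]

    @property
    def n_positions(self) -> int:
        return sum(e - s + 1 for _, s, e in self.regions)

    def _locate(self, chrom: str, pos: int) -> tuple[int, int] | None:
        for ri, (c, s, e) in enumerate(self.regions):
            if c == chrom and s <= pos <= e:
                return ri, pos - s
        return None

    def base_counts(self, chrom: str, pos: int) -> np.ndarray:
        loc = self._locate(chrom, pos)
        if loc is None:
            raise KeyError(f"{chrom}:{pos} outside pileup regions")
        ri, off = loc
        return self.counts[ri][off]

    def informative(self, chrom: str, pos: int) -> int:
        c = self.base_counts(chrom, pos)
        return int(c.sum() - c[4])

    def contains(self, chrom: str, pos: int) -> bool:
        return self._locate(chrom, pos) is not None


def build_pileup(
    molecules: ConsensusSet, targets: list[TargetInterval]
) -> Pileup:
    """Accumulate consensus base counts over target intervals.

    Positions outside the targets are skipped; molecules extending past a
    target edge contribute only their in-target positions.
    """
    panel = molecules.panel
    cidx = panel.contig_index
    regions, mats = [], []
    ends = molecules.start + molecules.length - 1
    diff_chrom = molecules.chrom[molecules.diff_mol]
    for t in targets:
        s1, e1 = t.start + 1, t.end  # 1-based inclusive
        L = e1 - s1 + 1
        cid = cidx[t.chrom]
        m = molecules.chrom == cid
        lo = np.clip(molecules.start[m] - s1, 0, L)
        hi = np.clip(ends[m] - s1 + 1, 0, L)
        cover = np.zeros(L + 1, dtype=np.int64)
        np.add.at(cover, lo, 1)
        np.add.at(cover, hi, -1)
        depth = np.cumsum(cover[:-1])

        mat = np.zeros((L, 5), dtype=np.int64)
        dm = (diff_chrom == cid) & (molecules.diff_pos >= s1) & (molecules.diff_pos <= e1)
        np.add.at(mat, (molecules.diff_pos[dm] - s1, molecules.diff_base[dm]), 1)
        ref = panel.ref_slice(t.chrom, s1, L)
        mat[np.arange(L), ref] += depth - mat.sum(axis=1)
        regions.append((t.chrom, s1, e1))
        mats.append(mat)
    return Pileup(panel, regions, mats)


# ---------------------------------------------------------------------------
# germline genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Buccal (normal) evidence per locus: alt-allele fraction + coverage.

    ``vafs`` maps (chrom, pos, alt base) to the buccal VAF; ``covered``
    lists loci with adequate buccal coverage.  Loci absent from ``covered``
    are germline-unevaluable.
    """

    vafs: dict[tuple[str, int, str], float]
    covered: set[tuple[str, int]]

    def buccal_vaf(self, chrom: str, pos: int, alt: str) -> float | None:
        if (chrom, pos) not in self.covered:
            return None
        return self.vafs.get((chrom, pos, alt), 0.0)

    def variant_loci(self, threshold: float = GERMLINE_VAF_THRESHOLD) -> set[tuple[str, int]]:
        return {(c, p) for (c, p, _), v in self.vafs.items() if v >= threshold}

    @classmethod
    def from_vcf(cls, path, panel: PanelDesign | None = None) -> "GenotypeTable":
        """Load diploid genotypes from a VCF; GT 0/1 -> VAF 0.5, 1/1 -> 1.0.

        Every locus present in the VCF (including 0/0 records) counts as
        covered.  When ``panel`` is given, all gene-target positions count
        as covered too: the buccal library is captured with the same panel,
        so absence of a record there asserts hom-ref rather than no data.
        """
        vafs: dict[tuple[str, int, str], float] = {}
        covered: set[tuple[str, int]] = set()
        if panel is not None:
            for t in panel.targets:
                covered.update((t.chrom, p) for p in range(t.start + 1, t.end + 1))
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                covered.add((rec.chrom, rec.pos))
                for sample in rec.samples.values():
                    gt = [a for a in (sample.get("GT") or ()) if a is not None]
                    if not gt or not rec.alts:
                        continue
                    n_alt = sum(1 for a in gt if a > 0)
                    if n_alt:
                        vafs[(rec.chrom, rec.pos, rec.alts[0])] = n_alt / len(gt)
        return cls(vafs=vafs, covered=covered)

    @classmethod
    def from_pileup(cls, pileup: Pileup, min_depth: int = 20) -> "GenotypeTable":
        """Derive buccal evidence from a normal-sample pileup."""
        vafs: dict[tuple[str, int, str], float] = {}
        covered: set[tuple[str, int]] = set()
        for (chrom, s1, e1), mat in zip(pileup.regions, pileup.counts):
            informative = mat[:, :4].sum(axis=1)
            ref = pileup.panel.ref_slice(chrom, s1, e1 - s1 + 1)
            for off in np.flatnonzero(informative >= min_depth):
                pos = s1 + int(off)
                covered.add((chrom, pos))
                for b in range(4):
                    if b != ref[off] and mat[off, b] > 0:
                        vafs[(chrom, pos, BASES[b])] = mat[off, b] / informative[off]
        return cls(vafs=vafs, covered=covered)


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_molecules: int
    informative_molecules: int
    p_value: float
    status: str  # somatic | germline | germline-unevaluable | artifact

    def __post_init__(self):
        if self.alt_molecules > self.informative_molecules:
            raise ValueError("alt exceeds informative molecule count")

    @property
    def vaf(self) -> float:
        return self.alt_molecules / max(self.informative_molecules, 1)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def call_somatic(
    pileup: Pileup,
    germline: GenotypeTable,
    error_model,
    alpha: float = 0.05,
    min_alt_molecules: int = 2,
    germline_threshold: float = GERMLINE_VAF_THRESHOLD,
    n_tests: int | None = None,
) -> list[VariantCall]:
    """Binomial discovery against background error with germline subtraction.

    A site is somatic when the alt molecule count reaches
    ``min_alt_molecules``, the one-sided binomial tail against the
    background rate survives Bonferroni correction over ``n_tests``
    (default: all pileup positions), and the buccal VAF for that alt is
    below ``germline_threshold``.  Sites failing the buccal check are
    flagged germline; sites without buccal coverage are retained flagged
    ``germline-unevaluable``.
    """
    rate = error_model.rate
    if rate <= 0:
        raise ValueError("error model rate must be > 0 (floored)")
    m = n_tests if n_tests is not None else pileup.n_positions
    calls: list[VariantCall] = []
    n_uneval = 0
    for (chrom, s1, e1), mat in zip(pileup.regions, pileup.counts):
        L = e1 - s1 + 1
        ref = pileup.panel.ref_slice(chrom, s1, L)
        informative = mat[:, :4].sum(axis=1)
        for b in range(4):
            cand = np.flatnonzero((mat[:, b] >= min_alt_molecules) & (ref != b))
            if len(cand) == 0:
                continue
            pv = stats.binom.sf(mat[cand, b] - 1, informative[cand], rate)
            for off, p in zip(cand, pv):
                if p > alpha / m:
                    continue
                pos = s1 + int(off)
                alt = BASES[b]
                gvaf = germline.buccal_vaf(chrom, pos, alt)
                if gvaf is None:
                    status = "germline-unevaluable"
                    n_uneval += 1
                elif gvaf >= germline_threshold:
                    status = "germline"
                else:
                    status = "somatic"
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=pos,
                        ref=BASES[ref[off]],
                        alt=alt,
                        alt_molecules=int(mat[off, b]),
                        informative_molecules=int(informative[off]),
                        p_value=float(p),
                        status=status,
                    )
                )
    if n_uneval:
        warnings.warn(f"{n_uneval} calls lack buccal coverage (germline-unevaluable)")
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


def genotype_tracked(
    pileup: Pileup, tracked_variants: list[tuple[str, int, str, str]]
) -> pd.DataFrame:
    """Threshold-free counts for every tracked reporter variant.

    Rows report alt molecules, informative molecules and VAF; a reporter
    with zero informative coverage is *missing* (VAF NaN), which is
    distinct from an observed VAF of 0.
    """
    if not tracked_variants:
        raise ValueError("tracked variant list is empty")
    rows = []
    for chrom, pos, ref, alt in tracked_variants:
        if pileup.contains(chrom, pos):
            c = pileup.base_counts(chrom, pos)
            informative = int(c.sum() - c[4])
            altn = int(c[BASES.index(alt)])
        else:
            informative, altn = 0, 0
        missing = informative == 0
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_molecules": 0 if missing else altn,
                "informative_molecules": informative,
                "vaf": np.nan if missing else altn / informative,
                "missing": missing,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phased pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasedPair:
    """Two somatic variants <= 100 bp apart observed in cis."""

    chrom: str
    pos_a: int
    alt_a: str
    pos_b: int
    alt_b: str
    support: int  # molecules carrying both alts
    covering: int  # molecules covering both positions

    def __post_init__(self):
        if abs(self.pos_a - self.pos_b) > 100:
            raise ValueError("phased pair members must lie within 100 bp")
        if self.support > self.covering:
            raise ValueError("support exceeds double-covering molecules")


def detect_phased_pairs(
    molecules: ConsensusSet,
    somatic_variants,
    max_distance: int = 100,
    min_support: int = 1,
) -> list[PhasedPair]:
    """Evaluate all variant pairs within ``max_distance`` for cis support.

    ``somatic_variants`` may be :class:`VariantCall` objects or
    (chrom, pos, ref, alt) tuples.  A pair is emitted when at least
    ``min_support`` consensus molecules carry both alt bases.
    """
    var = [
        (v.chrom, v.pos, v.alt) if isinstance(v, VariantCall) else (v[0], v[1], v[3])
        for v in somatic_variants
    ]
    cidx = molecules.panel.contig_index
    ends = molecules.start + molecules.length - 1
    dkey = (
        molecules.diff_mol.astype(np.int64) << 28
        | molecules.diff_pos.astype(np.int64) << 3
        | molecules.diff_base.astype(np.int64)
    )
    dkey = np.sort(dkey)

    def has_alt(mols: np.ndarray, pos: int, alt: str) -> np.ndarray:
        q = mols.astype(np.int64) << 28 | np.int64(pos) << 3 | np.int64(BASES.index(alt))
        j = np.searchsorted(dkey, q)
        return (j < len(dkey)) & (dkey[np.minimum(j, len(dkey) - 1)] == q)

    pairs: list[PhasedPair] = []
    for i in range(len(var)):
        for j in range(i + 1, len(var)):
            (ca, pa, aa), (cb, pb, ab) = var[i], var[j]
            if ca != cb or abs(pa - pb) > max_distance or (pa, aa) == (pb, ab):
                continue
            lo, hi = min(pa, pb), max(pa, pb)
            cid = cidx[ca]
            cover = np.flatnonzero(
                (molecules.chrom == cid) & (molecules.start <= lo) & (ends >= hi)
            )
            support = int((has_alt(cover, pa, aa) & has_alt(cover, pb, ab)).sum())
            if support >= min_support:
                a_first = pa <= pb
                pairs.append(
                    PhasedPair(
                        chrom=ca,
                        pos_a=pa if a_first else pb,
                        alt_a=aa if a_first else ab,
                        pos_b=pb if a_first else pa,
                        alt_b=ab if a_first else aa,
                        support=support,
                        covering=int(len(cover)),
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# plasma vs tissue comparison
# ---------------------------------------------------------------------------


def compare_variant_sets(
    plasma_calls, tissue_calls, panel_genes: list[TargetInterval]
) -> dict:
    """Overlap of plasma and tissue variant sets within panel genes.

    Variant identity is (chrom, pos, ref, alt); concordance is the shared
    fraction of tissue calls that fall in panel genes, mirroring a
    tissue-vs-plasma validation comparison.
    """

    def in_panel(v) -> bool:
        chrom, pos = v[0], v[1]
        return any(t.chrom == chrom and t.start < pos <= t.end for t in panel_genes)

    def keyset(calls) -> set:
        out = set()
        for v in calls:
            k = v.key if isinstance(v, VariantCall) else tuple(v)
            if in_panel(k):
                out.add(k)
        return out

    plasma = keyset(plasma_calls)
    tissue = keyset(tissue_calls)
    shared = plasma & tissue
    return {
        "shared": len(shared),
        "plasma_only": len(plasma - tissue),
        "tissue_only": len(tissue - plasma),
        "concordance": len(shared) / len(tissue) if tissue else float("nan"),
    }
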