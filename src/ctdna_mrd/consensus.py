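"""UMI family grouping, consensus base calling and background error estimation.

Reads sharing (contig, unclipped 5' start, strand, UMI) derive from one
source cfDNA molecule; a majority vote within each family cancels
polymerase and sequencing errors, which is the digital error correction
that makes sub-percent variant detection possible.  Families below a
minimum size (default 3) are discarded; votes below a 2/3 plurality are
masked to N rather than guessed.

Two code paths produce identical results:

* :func:`group_umi_families` + :func:`collapse_families` — explicit,
  per-read objects; handles ragged member extents and UMI edit-distance
  merging; the reference implementation for small data.
* :func:`consensus_collapse` — vectorised engine over a
  :class:`~ctdna_mrd.reads.ReadBatch`; votes only at positions where some
  member differs from the reference, which is exact because everywhere
  else the vote is unanimous for the reference base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BASES, PanelDesign
from .reads import ReadBatch, ReadRecord, UMI_LENGTH

MIN_FAMILY_DEFAULT = 3
MAJORITY_FRAC_DEFAULT = 2.0 / 3.0


# ---------------------------------------------------------------------------
# explicit path
# ---------------------------------------------------------------------------


@dataclass
class UmiFamily:
    """Reads sharing (contig, 5' start, strand, UMI)."""

    chrom: str
    start: int  # 1-based leftmost
    strand: str
    umi: str
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class ConsensusMolecule:
    """Error-corrected representation of one source molecule.

    ``seq`` spans the union of member coverage starting at ``start``
    (1-based); positions whose vote fails the plurality rule hold N.
    """

    chrom: str
    start: int
    strand: str
    umi: str
    family_size: int
    seq: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base_at(self, pos: int) -> int:
        """Base code at a 1-based position (N outside coverage)."""
        if self.start <= pos <= self.end:
            return int(self.seq[pos - self.start])
        return 4


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def group_umi_families(
    reads, umi_edit_tolerance: int = 0
) -> list[UmiFamily]:
    """Partition coordinate-grouped reads into UMI families.

    With ``umi_edit_tolerance`` >= 1, UMIs within that Hamming distance at
    the same position are merged directionally: the smaller family is
    absorbed into the larger when ``size_small <= size_large / 2 + 1``
    (sequencing errors on the UMI itself produce low-count satellites of a
    real family).  Reads whose UMI is not 10 nt are excluded with a warning.
    """
    fams: dict[tuple, UmiFamily] = {}
    n_bad = 0
    for r in reads:
        if len(r.umi) != UMI_LENGTH:
            n_bad += 1
            continue
        key = (r.chrom, r.start, r.strand, r.umi)
        fam = fams.get(key)
        if fam is None:
            fam = fams[key] = UmiFamily(r.chrom, r.start, r.strand, r.umi)
        fam.reads.append(r)
    if n_bad:
        warnings.warn(f"excluded {n_bad} reads with UMI length != {UMI_LENGTH}")

    if umi_edit_tolerance <= 0:
        return list(fams.values())

    # directional merge within each positional group
    by_pos: dict[tuple, list[UmiFamily]] = {}
    for fam in fams.values():
        by_pos.setdefault((fam.chrom, fam.start, fam.strand), []).append(fam)
    out: list[UmiFamily] = []
    for group in by_pos.values():
        group.sort(key=lambda f: (-f.size, f.umi))
        merged: list[UmiFamily] = []
        for fam in group:
            target = None
            for big in merged:
                if (
                    _hamming(big.umi, fam.umi) <= umi_edit_tolerance
                    and fam.size <= big.size / 2 + 1
                ):
                    target = big
                    break
            if target is None:
                merged.append(fam)
            else:
                target.reads.extend(fam.reads)
        out.extend(merged)
    return out


def collapse_families(
    families: list[UmiFamily],
    min_family: int = MIN_FAMILY_DEFAULT,
    majority_frac: float = MAJORITY_FRAC_DEFAULT,
) -> list[ConsensusMolecule]:
    """Majority-vote consensus per family; families below ``min_family`` drop.

    At each covered position the consensus is the plurality base among
    A/C/G/T votes of covering members if its fraction of covering members
    reaches ``majority_frac``; ties and weaker pluralities yield N.  Each
    retained molecule counts once downstream regardless of family size.
    """
    if min_family < 1:
        raise ValueError("min_family must be >= 1")
    out = []
    for fam in families:
        if fam.size < min_family:
            continue
        lo = fam.start
        hi = max(r.end for r in fam.reads)
        L = hi - lo + 1
        counts = np.zeros((L, 5), dtype=np.int64)
        covering = np.zeros(L, dtype=np.int64)
        for r in fam.reads:
            off = r.start - lo
            for k, b in enumerate(r.seq):
                counts[off + k, BASES.index(b)] += 1
            covering[off : off + len(r.seq)] += 1
        seq = np.full(L, 4, dtype=np.uint8)
        acgt = counts[:, :4]
        best = acgt.max(axis=1)
        winner = acgt.argmax(axis=1)
        unique_max = (acgt == best[:, None]).sum(axis=1) == 1
        ok = (covering > 0) & unique_max & (best >= majority_frac * covering - 1e-9)
        seq[ok] = winner[ok]
        out.append(
            ConsensusMolecule(fam.chrom, fam.start, fam.strand, fam.umi, fam.size, seq)
        )
    return out


# ---------------------------------------------------------------------------
# columnar engine
# ---------------------------------------------------------------------------


@dataclass
class ConsensusSet:
    """Columnar consensus molecules: placement + sparse diffs vs reference.

    ``diff_base`` 0-3 are alt base calls, 4 marks an N (failed vote) at that
    position; all other covered positions equal the reference.  Arrays are
    sorted by (molecule, position).
    """

    panel: PanelDesign
    chrom: np.ndarray
    start: np.ndarray
    length: np.ndarray
    strand: np.ndarray
    umi: np.ndarray
    family_size: np.ndarray
    diff_mol: np.ndarray
    diff_pos: np.ndarray
    diff_base: np.ndarray
    _site_index: dict = field(default_factory=dict, repr=False)

    @property
    def n_molecules(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        """1-based inclusive right ends."""
        return self.start + self.length - 1

    def _chrom_sorted(self, cid: int):
        cached = self._site_index.get(cid)
        if cached is None:
            m = np.flatnonzero(self.chrom == cid)
            starts = np.sort(self.start[m])
            ends = np.sort(self.start[m] + self.length[m] - 1)
            cached = self._site_index[cid] = (starts, ends)
        return cached

    def depth_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Consensus molecules covering each 1-based position."""
        cid = self.panel.contig_index[chrom]
        starts, ends = self._chrom_sorted(cid)
        pos = np.asarray(pos)
        return np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="left"
        )

    def site_counts(self, sites: list[tuple[str, int]]) -> pd.DataFrame:
        """Per-site molecule counts by base (columns A,C,G,T,N, depth, ref)."""
        cidx = self.panel.contig_index
        key_diff = self.chrom[self.diff_mol].astype(np.int64) << 40 | self.diff_pos
        order = np.argsort(key_diff, kind="stable")
        kd = key_diff[order]
        db = self.diff_base[order]
        rows = []
        for chrom, pos in sites:
            depth = int(self.depth_at(chrom, np.array([pos]))[0])
            key = np.int64(cidx[chrom]) << 40 | np.int64(pos)
            lo, hi = np.searchsorted(kd, [key, key + 1])
            cnt = np.bincount(db[lo:hi], minlength=5)
            ref = self.panel.ref_base(chrom, pos)
            row = {"chrom": chrom, "pos": pos, "depth": depth, "ref": BASES[ref]}
            for b in range(5):
                row[BASES[b]] = int(cnt[b]) if b != ref else depth - int(cnt.sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_explicit(self) -> list[ConsensusMolecule]:
        names = self.panel.contig_names
        out = []
        for i in range(self.n_molecules):
            cname = names[self.chrom[i]]
            seq = self.panel.ref_slice(cname, int(self.start[i]), int(self.length[i])).copy()
            lo, hi = np.searchsorted(self.diff_mol, [i, i + 1])
            seq[self.diff_pos[lo:hi] - self.start[i]] = self.diff_base[lo:hi]
            out.append(
                ConsensusMolecule(
                    cname,
                    int(self.start[i]),
                    "+-"[self.strand[i]],
                    "",
                    int(self.family_size[i]),
                    seq,
                )
            )
        return out


def consensus_collapse(
    batch: ReadBatch,
    min_family: int = MIN_FAMILY_DEFAULT,
    majority_frac: float = MAJORITY_FRAC_DEFAULT,
    umi_tolerance: int = 0,
) -> ConsensusSet:
    """Group a read batch into UMI families and call consensus molecules.

    Exact equivalent of the explicit grouping + collapse path: families key
    on (contig, 5' start, strand, UMI), votes at each position run over the
    members whose extent covers it.
    """
    if min_family < 1:
        raise ValueError("min_family must be >= 1")
    key = (
        batch.chrom.astype(np.int64) << 55
        | batch.strand.astype(np.int64) << 54
        | batch.start.astype(np.int64) << 20
        | batch.umi.astype(np.int64)
    )
    if umi_tolerance > 0:
        key = _merge_umis(batch, key, umi_tolerance)
    uniq, fam_of_read = np.unique(key, return_inverse=True)
    n_fam = len(uniq)
    fam_size = np.bincount(fam_of_read, minlength=n_fam)

    order = np.argsort(fam_of_read, kind="stable")
    first = np.zeros(n_fam, dtype=np.int64)
    first[fam_of_read[order][::-1]] = order[::-1]  # first read index per family
    bounds = np.concatenate([[0], np.cumsum(fam_size)])
    # member lengths per family, sorted, for positional covering counts
    # (members share the 5' start but may differ in fragment extent)
    lenkey = fam_of_read.astype(np.int64) << 25 | batch.length.astype(np.int64)
    lenkey_sorted = np.sort(lenkey)
    fam_maxlen = np.maximum.reduceat(batch.length[order], bounds[:-1])

    keep = fam_size >= min_family
    new_id = np.cumsum(keep) - 1  # family -> kept-molecule index
    kept_first = first[keep]
    kept_fam = np.flatnonzero(keep)

    out_chrom = batch.chrom[kept_first]
    out_start = batch.start[kept_first]
    out_length = fam_maxlen[keep]  # union of member coverage
    out_strand = batch.strand[kept_first]
    out_umi = batch.umi[kept_first]
    out_size = fam_size[keep]

    # votes at positions where any member differs from reference
    dfam = fam_of_read[batch.diff_read]
    m = keep[dfam]
    dmol = new_id[dfam[m]]
    dpos = batch.diff_pos[m]
    dbase = batch.diff_base[m]

    if len(dmol) == 0:
        empty = np.zeros(0, dtype=np.int64)
        return ConsensusSet(
            batch.panel, out_chrom, out_start, out_length, out_strand, out_umi,
            out_size.astype(np.int64), empty, empty.copy(), np.zeros(0, np.uint8),
        )

    vkey = dmol.astype(np.int64) << 25 | dpos  # contigs are < 2**25 bp
    cand, inv = np.unique(vkey, return_inverse=True)
    counts = np.zeros((len(cand), 5), dtype=np.int64)
    np.add.at(counts, (inv, dbase), 1)

    cmol = (cand >> 25).astype(np.int64)
    cpos = (cand & (2**25 - 1)).astype(np.int64)
    # members covering the candidate position: those whose extent reaches it
    fam_id = kept_fam[cmol]
    need_len = cpos - out_start[cmol] + 1
    n_short = np.searchsorted(
        lenkey_sorted, fam_id.astype(np.int64) << 25 | need_len.astype(np.int64)
    ) - bounds[fam_id]
    covering = out_size[cmol].astype(np.int64) - n_short
    refb = _ref_base_codes(batch.panel, out_chrom[cmol], cpos)
    acgt = counts[:, :4].copy()
    acgt[np.arange(len(cand)), refb] += covering - counts.sum(axis=1)

    best = acgt.max(axis=1)
    winner = acgt.argmax(axis=1).astype(np.uint8)
    unique_max = (acgt == best[:, None]).sum(axis=1) == 1
    ok = unique_max & (best >= majority_frac * covering - 1e-9)
    call = np.where(ok, winner, np.uint8(4))

    emit = call != refb
    dm, dp, db = cmol[emit], cpos[emit], call[emit]
    o = np.lexsort((dp, dm))
    return ConsensusSet(
        batch.panel,
        out_chrom,
        out_start,
        out_length,
        out_strand,
        out_umi,
        out_size.astype(np.int64),
        dm[o],
        dp[o],
        db[o].astype(np.uint8),
    )


def _ref_base_codes(panel: PanelDesign, chrom_id: np.ndarray, pos: np.ndarray) -> np.ndarray:
    out = np.empty(len(pos), dtype=np.int64)
    for cid, name in enumerate(panel.contig_names):
        m = chrom_id == cid
        if m.any():
            out[m] = panel.sequences[name][pos[m] - 1]
    return out


def _merge_umis(batch: ReadBatch, key: np.ndarray, tolerance: int) -> np.ndarray:
    """Directional UMI merging on the packed keys (small-scale path)."""
    poskey = key >> 20
    umis = (key & (2**20 - 1)).astype(np.int64)
    out = key.copy()
    order = np.argsort(poskey, kind="stable")
    bounds = np.flatnonzero(np.diff(poskey[order])) + 1
    for grp in np.split(order, bounds):
        u, inv = np.unique(umis[grp], return_inverse=True)
        if len(u) == 1:
            continue
        sizes = np.bincount(inv)
        idx = np.argsort(-sizes, kind="stable")
        canon = {}
        reprs: list[int] = []
        for i in idx:
            target = None
            for j in reprs:
                if _umi_hamming(int(u[i]), int(u[j])) <= tolerance and sizes[i] <= sizes[j] / 2 + 1:
                    target = j
                    break
            if target is None:
                reprs.append(i)
                canon[i] = i
            else:
                canon[i] = target
        mapped = np.array([u[canon[i]] for i in inv])
        out[grp] = (poskey[grp] << 20) | mapped
    return out


def _umi_hamming(a: int, b: int) -> int:
    x = a ^ b
    d = 0
    for i in range(UMI_LENGTH):
        if (x >> (2 * i)) & 3:
            d += 1
    return d


# ---------------------------------------------------------------------------
# background error model
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Post-consensus background alt-call rate at variant-free sites.

    The pooled rate is the total of each site's most frequent alt-molecule
    count over total molecules; when no alt molecule is observed the rate is
    floored at 0.5 / total so downstream binomial tests remain defined.
    """

    rate: float
    n_sites: int
    total_molecules: int
    alt_molecules: int
    per_site: pd.DataFrame

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate outside [0, 1]")


def estimate_background_error(
    molecules: ConsensusSet,
    flanking_sites: list[tuple[str, int]],
    germline_variant_loci: set[tuple[str, int]] | None = None,
) -> ErrorModel:
    """Pool the most-frequent-alt consensus rate across variant-free sites.

    ``flanking_sites`` are loci adjacent to interrogated SNPs where no true
    variant is expected; sites overlapping a germline variant in any
    contributing individual are excluded with a warning.
    """
    germline_variant_loci = germline_variant_loci or set()
    used = [s for s in flanking_sites if s not in germline_variant_loci]
    dropped = len(flanking_sites) - len(used)
    if dropped:
        warnings.warn(f"excluded {dropped} flanking sites overlapping germline variants")
    if not used:
        raise ValueError("no usable flanking sites")
    tab = molecules.site_counts(used)
    alt_cols = [b for b in "ACGT"]
    alt_count = np.zeros(len(tab), dtype=np.int64)
    for i, row in tab.iterrows():
        counts = {b: row[b] for b in alt_cols if b != row["ref"]}
        alt_count[i] = max(counts.values()) if counts else 0
    informative = tab["depth"].to_numpy() - tab["N"].to_numpy()
    total = int(informative.sum())
    alts = int(alt_count.sum())
    rate = alts / total if alts > 0 else 0.5 / max(total, 1)
    per_site = tab.assign(
        informative=informative,
        most_frequent_alt=alt_count,
        rate=np.where(informative > 0, alt_count / np.maximum(informative, 1), np.nan),
    )
    return ErrorModel(
        rate=rate,
        n_sites=len(used),
        total_molecules=total,
        alt_molecules=alts,
        per_site=per_site,
    )
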