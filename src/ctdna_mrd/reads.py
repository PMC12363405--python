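"""Aligned UMI-tagged reads: explicit records, a columnar batch form, and SAM I/O.

Two equivalent representations are used:

* :class:`ReadRecord` — one object per read, convenient for small data and
  for round-tripping through SAM.
* :class:`ReadBatch` — a struct-of-arrays form in which each read is stored
  as (contig, 1-based start, length, strand, UMI code) plus a sparse list of
  differences from the reference sequence.  Deep UMI-family simulations and
  the consensus caller operate on this form; it is exact (every read's full
  base sequence is recoverable) while keeping memory proportional to the
  number of non-reference bases rather than to total sequenced bases.

UMIs are 10-mers carried in the SAM ``RX`` tag; a fallback accepts the UMI
as the read-name suffix after the last ``:`` (both dialects occur in the
wild).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .panel import BASES, PanelDesign, decode_seq

UMI_LENGTH = 10


def encode_umi(umi: str) -> int:
    if len(umi) != UMI_LENGTH:
        raise ValueError(f"UMI length {len(umi)} != {UMI_LENGTH}")
    code = 0
    for i, b in enumerate(umi):
        code |= BASES.index(b) << (2 * i)
    return code


def decode_umi(code: int) -> str:
    return "".join(BASES[(code >> (2 * i)) & 3] for i in range(UMI_LENGTH))


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read with an attached UMI (position 1-based, no indels)."""

    name: str
    chrom: str
    start: int  # 1-based leftmost aligned position
    strand: str  # '+' or '-'
    seq: str
    umi: str

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("position must be >= 1")
        if set(self.seq) - set(BASES):
            raise ValueError("bases must be in {A,C,G,T,N}")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost position."""
        return self.start + len(self.seq) - 1


@dataclass
class ReadBatch:
    """Columnar read set: per-read placement plus sparse diffs vs reference.

    ``diff_*`` arrays are sorted by (read index, position); a position absent
    from the diffs carries the reference base.  ``molecule`` is optional
    generator bookkeeping (source-molecule id per read) and is ignored by
    all downstream computation.
    """

    panel: PanelDesign
    chrom: np.ndarray
    start: np.ndarray
    length: np.ndarray
    strand: np.ndarray
    umi: np.ndarray
    diff_read: np.ndarray
    diff_pos: np.ndarray
    diff_base: np.ndarray
    molecule: np.ndarray | None = None

    @property
    def n_reads(self) -> int:
        return len(self.start)

    @property
    def total_bases(self) -> int:
        return int(self.length.sum())

    def read_seq(self, i: int) -> np.ndarray:
        """Materialised base codes of read ``i``."""
        cname = self.panel.contig_names[self.chrom[i]]
        seq = self.panel.ref_slice(cname, int(self.start[i]), int(self.length[i])).copy()
        lo, hi = np.searchsorted(self.diff_read, [i, i + 1])
        seq[self.diff_pos[lo:hi] - self.start[i]] = self.diff_base[lo:hi]
        return seq

    def to_records(self) -> list[ReadRecord]:
        names = self.panel.contig_names
        return [
            ReadRecord(
                name=f"m{self.molecule[i] if self.molecule is not None else i}.r{i}",
                chrom=names[self.chrom[i]],
                start=int(self.start[i]),
                strand="+-"[self.strand[i]],
                seq=decode_seq(self.read_seq(i)),
                umi=decode_umi(int(self.umi[i])),
            )
            for i in range(self.n_reads)
        ]

    # -- SAM ----------------------------------------------------------------
    def write_sam(self, path) -> None:
        """Write coordinate-sorted SAM with the UMI in the RX tag."""
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": int(l)} for c, l in self.panel.contig_lengths.items()
            ],
        }
        order = np.lexsort((self.start, self.chrom))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in order:
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"m{self.molecule[i] if self.molecule is not None else i}.r{i}"
                a.query_sequence = decode_seq(self.read_seq(int(i)))
                a.flag = 16 if self.strand[i] else 0
                a.reference_id = int(self.chrom[i])
                a.reference_start = int(self.start[i]) - 1
                a.mapping_quality = 60
                a.cigarstring = f"{int(self.length[i])}M"
                a.set_tag("RX", decode_umi(int(self.umi[i])))
                out.write(a)


def batch_from_records(records: list[ReadRecord], panel: PanelDesign) -> ReadBatch:
    """Build the columnar form from explicit reads (diffs computed vs reference)."""
    cidx = panel.contig_index
    n = len(records)
    chrom = np.zeros(n, dtype=np.int16)
    start = np.zeros(n, dtype=np.int64)
    length = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    umi = np.zeros(n, dtype=np.uint32)
    d_read, d_pos, d_base = [], [], []
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    for i, r in enumerate(records):
        chrom[i] = cidx[r.chrom]
        start[i] = r.start
        length[i] = len(r.seq)
        strand[i] = 0 if r.strand == "+" else 1
        umi[i] = encode_umi(r.umi)
        seq = lut[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
        ref = panel.ref_slice(r.chrom, r.start, len(r.seq))
        mism = np.flatnonzero(seq != ref)
        d_read.append(np.full(len(mism), i, dtype=np.int64))
        d_pos.append(mism + r.start)
        d_base.append(seq[mism])
    return ReadBatch(
        panel=panel,
        chrom=chrom,
        start=start,
        length=length,
        strand=strand,
        umi=umi,
        diff_read=np.concatenate(d_read) if d_read else np.zeros(0, np.int64),
        diff_pos=np.concatenate(d_pos).astype(np.int64) if d_pos else np.zeros(0, np.int64),
        diff_base=np.concatenate(d_base) if d_base else np.zeros(0, np.uint8),
    )


def read_sam(path, panel: PanelDesign) -> ReadBatch:
    """Load aligned UMI-tagged reads from SAM/BAM into a :class:`ReadBatch`.

    Reads whose UMI is missing or not 10 nt are excluded with a warning, as
    are reads with indel/clip CIGARs (the assay model is match-only).
    """
    records: list[ReadRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            umi = aln.get_tag("RX") if aln.has_tag("RX") else aln.query_name.rsplit(":", 1)[-1]
            if len(umi) != UMI_LENGTH or set(umi) - set(BASES):
                skipped += 1
                continue
            if aln.cigartuples and any(op != 0 for op, _ in aln.cigartuples):
                skipped += 1
                continue
            records.append(
                ReadRecord(
                    name=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start + 1,
                    strand="-" if aln.is_reverse else "+",
                    seq=aln.query_sequence,
                    umi=umi,
                )
            )
    if skipped:
        warnings.warn(f"excluded {skipped} reads with unusable UMI or CIGAR")
    return batch_from_records(records, panel)
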