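"""Synthetic targeted-panel design: reference contigs, gene targets and SNP backbone.

The assay being modelled is a hybrid-capture panel for aggressive B-cell
lymphoma: a set of recurrently mutated genes for somatic variant discovery
plus a genome-wide backbone of common SNPs used for copy-number analysis and
sample-identity fingerprinting.  Because the pipeline is exercised on
simulated cfDNA, the "genome" here is a small deterministic random sequence
per contig; every coordinate convention (1-based internally, BED 0-based
half-open at I/O boundaries) matches the real-data formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGTN"
A, C, G, T, N = range(5)

#: default gene content: recurrently mutated DLBCL genes (42 targets)
DEFAULT_GENES = [
    "TP53", "MYD88", "CD79B", "CREBBP", "EP300", "EZH2", "KMT2D", "TNFRSF14",
    "B2M", "CARD11", "BCL2", "BCL6", "BCL10", "PIM1", "IGLL5", "SOCS1",
    "STAT6", "TNFAIP3", "CIITA", "GNA13", "SGK1", "TET2", "DNMT3A", "BTG1",
    "BTG2", "FOXO1", "MEF2B", "NOTCH1", "NOTCH2", "PRDM1", "IRF4", "ITPKB",
    "JAK2", "SF3B1", "FAT1", "XPO1", "CCND3", "MYC", "ID3", "TBL1XR1",
    "ZFP36L1", "KLHL6",
]

#: contigs of the synthetic genome; chosen to include the arms where the
#: assay's recurrent lesions live (17p loss, 12q gain, 16p loss)
DEFAULT_CONTIGS = ["chr1", "chr3", "chr6", "chr9", "chr12", "chr16", "chr17", "chr18"]


def encode_seq(s: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


def decode_seq(a: np.ndarray) -> str:
    return "".join(BASES[b] for b in a)


@dataclass(frozen=True)
class TargetInterval:
    """One capture target; start/end are 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SnpLocus:
    """A backbone SNP: 1-based position, ref/alt base codes, population AF."""

    chrom: str
    pos: int
    ref: int
    alt: int
    pop_af: float

    def __post_init__(self):
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValueError("population AF outside [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass
class PanelDesign:
    """Reference sequences + gene targets + SNP backbone + arm table."""

    contig_lengths: dict[str, int]
    sequences: dict[str, np.ndarray]
    targets: list[TargetInterval]
    backbone: list[SnpLocus]
    arms: pd.DataFrame  # columns: chrom, arm, start, end (0-based half-open)
    _seq_cache: dict = field(default_factory=dict, repr=False)

    # -- reference access ---------------------------------------------------
    def ref_base(self, chrom: str, pos: int) -> int:
        """Reference base code at a 1-based position."""
        return int(self.sequences[chrom][pos - 1])

    def ref_slice(self, chrom: str, start: int, length: int) -> np.ndarray:
        """Reference codes for [start, start+length), start 1-based."""
        return self.sequences[chrom][start - 1 : start - 1 + length]

    @property
    def contig_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.contig_lengths)}

    @property
    def contig_names(self) -> list[str]:
        return list(self.contig_lengths)

    def targets_by_gene(self) -> dict[str, TargetInterval]:
        return {t.name: t for t in self.targets}

    def target_positions(self) -> int:
        """Total number of reference positions under gene targets."""
        return sum(t.length for t in self.targets)

    def backbone_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.backbone],
                "pos": [s.pos for s in self.backbone],
                "ref": [BASES[s.ref] for s in self.backbone],
                "alt": [BASES[s.alt] for s in self.backbone],
                "pop_af": [s.pop_af for s in self.backbone],
            }
        )

    def arm_of(self, chrom: str, pos: int) -> str:
        """Arm label ('17p' style) containing a 1-based position."""
        hit = self.arms[
            (self.arms.chrom == chrom)
            & (self.arms.start < pos)
            & (pos <= self.arms.end)
        ]
        if hit.empty:
            return ""
        return hit.iloc[0]["arm"]

    # -- I/O ---------------------------------------------------------------
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                s = decode_seq(seq)
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")

    def write_targets_bed(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.targets:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\n")

    def write_backbone_bed(self, path) -> None:
        """Backbone loci as BED (0-based half-open, 1 bp per locus)."""
        with open(path, "w") as fh:
            for s in self.backbone:
                fh.write(
                    f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t"
                    f"{BASES[s.ref]}>{BASES[s.alt]};AF={s.pop_af:g}\n"
                )


def read_targets_bed(path) -> list[TargetInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"])
    return [
        TargetInterval(r.chrom, int(r.start), int(r.end), str(r.name))
        for r in df.itertuples()
    ]


def build_panel(
    seed: int = 0,
    genes: list[str] | None = None,
    target_length: int = 300,
    n_backbone: int = 1040,
    contigs: list[str] | None = None,
    contig_length: int = 1_200_000,
    backbone_af: float = 0.5,
) -> PanelDesign:
    """Construct the default desk-scale panel.

    Gene targets are laid out round-robin across contigs (TP53 pinned to the
    17p analogue), and ``n_backbone`` SNPs are spaced evenly across both arms
    of every contig.  ``backbone_af`` is the population allele frequency of
    every backbone SNP; the default 0.5 reflects that fingerprinting panels
    select maximally informative common SNPs.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else list(DEFAULT_GENES)
    contigs = list(contigs) if contigs is not None else list(DEFAULT_CONTIGS)

    contig_lengths = {c: contig_length for c in contigs}
    sequences = {
        c: rng.integers(0, 4, size=contig_length, dtype=np.uint8) for c in contigs
    }

    # arm table: p arm = first 45%, q arm = last 50% (centromere gap between)
    rows = []
    for c in contigs:
        L = contig_lengths[c]
        num = c.removeprefix("chr")
        rows.append({"chrom": c, "arm": f"{num}p", "start": 0, "end": int(0.45 * L)})
        rows.append({"chrom": c, "arm": f"{num}q", "start": int(0.50 * L), "end": L})
    arms = pd.DataFrame(rows)

    # gene targets: spaced within arms, avoiding backbone loci by construction
    targets = []
    for i, gene in enumerate(genes):
        if gene == "TP53" and "chr17" in contigs:
            # pin to the 17p analogue for the recurrent-loss story
            arm_row = arms[(arms.chrom == "chr17") & (arms.arm == "17p")].iloc[0]
            chrom, start = "chr17", int(arm_row["start"]) + 5_000
        else:
            chrom = contigs[i % len(contigs)]
            arm_row = arms[arms.chrom == chrom].iloc[i // len(contigs) % 2]
            slot = i // len(contigs)
            start = int(arm_row["start"]) + 10_000 + slot * 3 * target_length + (17 * i) % 97
        targets.append(TargetInterval(chrom, start, start + target_length, gene))

    # backbone SNPs: evenly spaced across arms, offset from gene targets
    per_arm = n_backbone // len(arms)
    extra = n_backbone - per_arm * len(arms)
    backbone: list[SnpLocus] = []
    taken = {(t.chrom, p) for t in targets for p in range(t.start + 1, t.end + 1)}
    for j, row in arms.iterrows():
        k = per_arm + (1 if j < extra else 0)
        span = row["end"] - row["start"]
        offs = np.linspace(0.1 * span, 0.95 * span, k).astype(int)
        for o in offs:
            pos = int(row["start"]) + int(o) + 1  # 1-based
            while (row["chrom"], pos) in taken:
                pos += 1
            ref = int(sequences[row["chrom"]][pos - 1])
            alt = (ref + 1 + int(rng.integers(0, 3))) % 4
            backbone.append(SnpLocus(row["chrom"], pos, ref, alt, backbone_af))
    backbone.sort(key=lambda s: (s.chrom, s.pos))

    return PanelDesign(contig_lengths, sequences, targets, backbone, arms)
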