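"""Sidecar file formats: germline VCF, sample sheets, backbone count tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import BASES, PanelDesign

SAMPLE_SHEET_COLUMNS = [
    "patient_id", "timepoint", "day", "cfdna_ng_per_ml", "reads_path",
]


def write_germline_vcf(path, panel: PanelDesign, genotypes: np.ndarray,
                       sample: str = "buccal") -> None:
    """Write backbone genotypes as a minimal VCF v4.2 (GT only).

    Hom-ref loci are included as 0/0 records so that coverage at every
    backbone locus is explicit.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in panel.contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp, g in zip(panel.backbone, genotypes):
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{BASES[snp.ref]}\t{BASES[snp.alt]}"
                f"\t.\tPASS\t.\tGT\t{gt_map[int(g)]}\n"
            )


def write_sample_sheet(path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    return df


def write_backbone_counts(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_backbone_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "depth", "ref_count", "alt_count"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"backbone count table missing columns: {sorted(missing)}")
    return df
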