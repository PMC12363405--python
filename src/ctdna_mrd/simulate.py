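"""Synthetic cfDNA cohort generator with full ground-truth bookkeeping.

Emulates the data a targeted UMI-based cfDNA assay produces: unique source
molecules drawn from panel targets with mononucleosomal fragment sizes,
PCR/sequencing duplication into UMI read families (shifted negative
binomial), independent per-base sequencing error, planted somatic variants
(optionally cis-phased), germline SNP genotypes on the backbone,
two-individual admixtures for dilution series, segmental copy-number
profiles, and clinical cohorts with response-dependent progression hazards.

Every random draw flows from one seed; per-sample substreams are derived
deterministically so that individual samples are reproducible in isolation.
The sidecar truth tables record what was planted, down to each molecule's
true alleles, so that parameter-recovery tests can reconcile pipeline output
against the generator exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import BASES, PanelDesign, TargetInterval
from .reads import ReadBatch

UMI_SPACE = 4**10  # 10-nt UMIs


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG for a labelled sub-experiment."""
    import hashlib

    spawn = [
        int.from_bytes(
            hashlib.blake2s(str(k).encode(), digest_size=4).digest(), "little"
        )
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


# ---------------------------------------------------------------------------
# configuration & truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Per-sample simulation parameters.

    ``n_molecules`` is the number of unique source molecules per gene target
    (for :func:`simulate_sample`) or per interrogated SNP site (for
    :func:`simulate_dilution`); family sizes follow a shifted negative
    binomial (minimum 1) with the given mean and dispersion.
    """

    panel: PanelDesign
    seed: int = 0
    n_molecules: int = 2000
    family_mean: float = 4.0
    family_dispersion: float = 2.0
    per_base_error: float = 0.003
    fragment_mean: float = 167.0
    fragment_sd: float = 40.0
    fragment_min: int = 50
    fragment_max: int = 400
    umi_length: int = 10

    def __post_init__(self):
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.family_mean < 1:
            raise ValueError("family sizes are >= 1, so family_mean must be >= 1")
        if not (0 < self.fragment_min <= self.fragment_max):
            raise ValueError("fragment length bounds must be positive and ordered")
        if self.fragment_mean <= 0 or self.fragment_sd < 0:
            raise ValueError("fragment length distribution must be positive")
        if self.umi_length != 10:
            raise ValueError("the assay uses 10-nt UMIs")


def surviving_family_fraction(cfg: SimConfig, min_family: int = 3) -> float:
    """P(family size >= min_family) under the shifted negative binomial."""
    if cfg.family_mean <= 1.0:
        return 1.0 if min_family <= 1 else 0.0
    r = cfg.family_dispersion
    p = r / (r + cfg.family_mean - 1.0)
    return float(stats.nbinom.sf(min_family - 2, r, p))


def molecules_for_consensus_depth(cfg: SimConfig, depth: int, min_family: int = 3) -> int:
    """Source molecules needed per site for an expected consensus depth."""
    return int(np.ceil(depth / surviving_family_fraction(cfg, min_family)))


def position_coverage_fraction(cfg: SimConfig, target_length: int, offset0: int) -> float:
    """P(a uniformly placed fragment covers a 0-based offset within a target).

    Integrates over the truncated-normal fragment length distribution; used
    to size simulations for a desired depth at a planted variant position.
    """
    lo, hi = cfg.fragment_min, min(cfg.fragment_max, target_length)
    if hi <= lo:
        return 1.0
    a = (lo - cfg.fragment_mean) / cfg.fragment_sd
    b = (hi - cfg.fragment_mean) / cfg.fragment_sd
    dist = stats.truncnorm(a, b, loc=cfg.fragment_mean, scale=cfg.fragment_sd)
    num = den = 0.0
    for L in range(lo, hi + 1):
        w = dist.cdf(L + 0.5) - dist.cdf(L - 0.5)
        starts = target_length - L + 1
        cov = min(offset0, target_length - L) - max(0, offset0 - L + 1) + 1
        num += w * max(cov, 0) / starts
        den += w
    return num / den


@dataclass(frozen=True)
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: int
    alt: int
    vaf: float

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("VAF outside [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref == alt")


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    copies: int

    def __post_init__(self):
        if self.copies < 0:
            raise ValueError("copy number must be >= 0")
        if self.start > self.end:
            raise ValueError("empty segment")


@dataclass
class TruthSet:
    """Planted ground truth for one patient/sample family."""

    somatic_variants: list[SomaticVariant] = field(default_factory=list)
    #: (index_a, index_b, cis co-occurrence probability)
    phased_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    #: individual -> alt-allele copies (0/1/2) aligned to panel.backbone
    germline_genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    #: timepoint label -> true tumour fraction scaling
    timepoint_burden: dict[str, float] = field(default_factory=dict)

    def validate(self, panel: PanelDesign) -> None:
        by_locus: dict[tuple[str, int], float] = {}
        for v in self.somatic_variants:
            if panel.ref_base(v.chrom, v.pos) != v.ref:
                raise ValueError(f"variant ref mismatch at {v.chrom}:{v.pos}")
            by_locus[(v.chrom, v.pos)] = by_locus.get((v.chrom, v.pos), 0.0) + v.vaf
        if any(s > 1.0 + 1e-9 for s in by_locus.values()):
            raise ValueError("overlapping variants at one locus with VAF sum > 1")
        for i, j, cis in self.phased_pairs:
            a, b = self.somatic_variants[i], self.somatic_variants[j]
            if a.chrom != b.chrom or abs(a.pos - b.pos) > 100:
                raise ValueError("phased pair members must lie within 100 bp in cis")
            if not 0.0 <= cis <= 1.0:
                raise ValueError("cis probability outside [0, 1]")

    def phase_group_of(self) -> dict[int, int]:
        """Variant index -> phase-group id (pairs share a group)."""
        group = {i: i for i in range(len(self.somatic_variants))}
        for i, j, _ in self.phased_pairs:
            group[j] = group[i]
        return group


@dataclass
class SampleTruth:
    """Sidecar bookkeeping emitted with every simulated read set."""

    molecules: pd.DataFrame  # chrom, start, length, strand, umi, family_size
    alleles: pd.DataFrame  # molecule, chrom, pos, base (true non-reference bases)
    variant_counts: pd.DataFrame  # chrom, pos, alt, covering, alt_molecules
    n_error_bases: int
    total_bases: int

    @property
    def raw_error_rate(self) -> float:
        return self.n_error_bases / max(self.total_bases, 1)

    def write(self, prefix) -> None:
        self.molecules.to_csv(f"{prefix}.molecules.tsv", sep="\t", index=False)
        self.alleles.to_csv(f"{prefix}.alleles.tsv", sep="\t", index=False)
        self.variant_counts.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)


def draw_genotypes(panel: PanelDesign, rng: np.random.Generator) -> np.ndarray:
    """Hardy–Weinberg genotypes (alt copies 0/1/2) over the backbone."""
    af = np.array([s.pop_af for s in panel.backbone])
    return rng.binomial(2, af).astype(np.int8)


# ---------------------------------------------------------------------------
# read emission (shared by sample and dilution simulators)
# ---------------------------------------------------------------------------


def _truncnorm_lengths(cfg: SimConfig, cap: int, n: int, rng) -> np.ndarray:
    hi = min(cfg.fragment_max, cap)
    lo = min(cfg.fragment_min, hi)
    if hi <= lo:
        return np.full(n, lo, dtype=np.int64)
    a = (lo - cfg.fragment_mean) / cfg.fragment_sd
    b = (hi - cfg.fragment_mean) / cfg.fragment_sd
    vals = stats.truncnorm.rvs(a, b, loc=cfg.fragment_mean, scale=cfg.fragment_sd,
                               size=n, random_state=rng)
    return np.clip(np.rint(vals), lo, hi).astype(np.int64)


def _ref_base_at(panel: PanelDesign, chrom_id: np.ndarray, pos: np.ndarray) -> np.ndarray:
    out = np.empty(len(pos), dtype=np.uint8)
    for cid, name in enumerate(panel.contig_names):
        m = chrom_id == cid
        if m.any():
            out[m] = panel.sequences[name][pos[m] - 1]
    return out


def _emit_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    mol_chrom: np.ndarray,
    mol_start: np.ndarray,
    mol_length: np.ndarray,
    mol_diff_mol: np.ndarray,
    mol_diff_pos: np.ndarray,
    mol_diff_base: np.ndarray,
) -> tuple[ReadBatch, np.ndarray, int, np.ndarray, np.ndarray]:
    """Amplify molecules into UMI families and apply sequencing error.

    Returns the read batch, per-molecule family sizes, the realised number
    of sequencing-error bases, and the per-molecule strand and UMI draws.
    """
    n_mol = len(mol_start)
    strand = rng.integers(0, 2, n_mol).astype(np.int8)
    umi = rng.integers(0, UMI_SPACE, n_mol, dtype=np.int64).astype(np.uint32)

    # shifted negative binomial family sizes (min 1)
    if cfg.family_mean <= 1.0:
        fam = np.ones(n_mol, dtype=np.int64)
    else:
        r = cfg.family_dispersion
        p = r / (r + cfg.family_mean - 1.0)
        fam = 1 + rng.negative_binomial(r, p, n_mol).astype(np.int64)

    mol_of_read = np.repeat(np.arange(n_mol), fam)
    n_reads = len(mol_of_read)
    r_chrom = mol_chrom[mol_of_read].astype(np.int16)
    r_start = mol_start[mol_of_read]
    r_length = mol_length[mol_of_read]
    r_strand = strand[mol_of_read]
    r_umi = umi[mol_of_read]

    # expand molecule alleles to every member read
    order = np.lexsort((mol_diff_pos, mol_diff_mol))
    md_mol = mol_diff_mol[order]
    md_pos = mol_diff_pos[order]
    md_base = mol_diff_base[order]
    d_cnt = np.bincount(md_mol, minlength=n_mol)
    d_start = np.concatenate([[0], np.cumsum(d_cnt)])[:-1]
    per_read = d_cnt[mol_of_read]
    rd_read = np.repeat(np.arange(n_reads), per_read)
    within = np.arange(per_read.sum()) - np.repeat(np.cumsum(per_read) - per_read, per_read)
    rd_idx = np.repeat(d_start[mol_of_read], per_read) + within
    rd_pos = md_pos[rd_idx]
    rd_base = md_base[rd_idx]
    rd_prio = np.zeros(len(rd_idx), dtype=np.int8)

    # sequencing errors: a uniform random subset of all sequenced bases flips
    # to one of the three other bases
    total = int(r_length.sum())
    n_err_draw = rng.binomial(total, cfg.per_base_error) if cfg.per_base_error > 0 else 0
    if n_err_draw:
        gpos = np.unique(rng.integers(0, total, n_err_draw))
        cum = np.concatenate([[0], np.cumsum(r_length)])
        e_read = np.searchsorted(cum, gpos, side="right") - 1
        e_pos = (r_start[e_read] + (gpos - cum[e_read])).astype(np.int64)
        # base currently on the read = molecule base (reference unless diffed)
        cur = _ref_base_at(cfg.panel, r_chrom[e_read], e_pos)
        if len(md_mol):
            key_md = md_mol.astype(np.int64) << 32 | md_pos.astype(np.int64)
            key_e = mol_of_read[e_read].astype(np.int64) << 32 | e_pos
            j = np.searchsorted(key_md, key_e)
            hit = (j < len(key_md)) & (key_md[np.minimum(j, len(key_md) - 1)] == key_e)
            cur[hit] = md_base[j[hit]]
        e_base = ((cur + 1 + rng.integers(0, 3, len(e_pos))) % 4).astype(np.uint8)
        rd_read = np.concatenate([rd_read, e_read])
        rd_pos = np.concatenate([rd_pos, e_pos])
        rd_base = np.concatenate([rd_base, e_base])
        rd_prio = np.concatenate([rd_prio, np.ones(len(e_pos), dtype=np.int8)])
        n_err = len(e_pos)
    else:
        n_err = 0

    # resolve per (read, pos): errors override molecule alleles; drop entries
    # that equal the reference (an error can restore the reference base)
    if len(rd_read):
        o = np.lexsort((rd_prio, rd_pos, rd_read))
        rd_read, rd_pos, rd_base = rd_read[o], rd_pos[o], rd_base[o]
        key = rd_read.astype(np.int64) * np.int64(2**40) + rd_pos
        last = np.concatenate([key[1:] != key[:-1], [True]])
        rd_read, rd_pos, rd_base = rd_read[last], rd_pos[last], rd_base[last]
        refb = _ref_base_at(cfg.panel, r_chrom[rd_read], rd_pos)
        keep = rd_base != refb
        rd_read, rd_pos, rd_base = rd_read[keep], rd_pos[keep], rd_base[keep]

    batch = ReadBatch(
        panel=cfg.panel,
        chrom=r_chrom,
        start=r_start.astype(np.int64),
        length=r_length.astype(np.int64),
        strand=r_strand,
        umi=r_umi,
        diff_read=rd_read.astype(np.int64),
        diff_pos=rd_pos.astype(np.int64),
        diff_base=rd_base.astype(np.uint8),
        molecule=mol_of_read,
    )
    return batch, fam, n_err, strand, umi


def _place_molecules(
    cfg: SimConfig, targets: list[TargetInterval], n_per_target: np.ndarray, rng
):
    """Draw fragment placements uniformly within each target interval."""
    chroms, starts, lengths, tgt_idx = [], [], [], []
    cidx = cfg.panel.contig_index
    for ti, (t, n) in enumerate(zip(targets, n_per_target)):
        if n == 0:
            continue
        L = _truncnorm_lengths(cfg, t.length, int(n), rng)
        s0 = rng.integers(0, t.length - L + 1)  # offset within target
        starts.append(t.start + 1 + s0)  # 1-based genomic
        lengths.append(L)
        chroms.append(np.full(int(n), cidx[t.chrom], dtype=np.int16))
        tgt_idx.append(np.full(int(n), ti, dtype=np.int32))
    return (
        np.concatenate(chroms),
        np.concatenate(starts).astype(np.int64),
        np.concatenate(lengths),
        np.concatenate(tgt_idx),
    )


# ---------------------------------------------------------------------------
# sample-level simulators
# ---------------------------------------------------------------------------


def simulate_sample(
    cfg: SimConfig,
    truth: TruthSet,
    tumour_fraction: float,
    individual: str = "patient",
    rng: np.random.Generator | None = None,
    targets: list[TargetInterval] | None = None,
) -> tuple[ReadBatch, SampleTruth]:
    """Simulate one plasma sample as aligned UMI-tagged reads + truth tables.

    Each source molecule covering a planted variant carries the alt allele
    with probability ``vaf * tumour_fraction``; members of a cis-phased pair
    co-occur on the same molecule with their configured cis probability.
    ``cfg.n_molecules`` molecules are drawn per target.
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction outside [0, 1]")
    targets = targets if targets is not None else cfg.panel.targets
    if not targets:
        raise ValueError("panel has no targets")
    truth.validate(cfg.panel)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    panel = cfg.panel
    cidx = panel.contig_index

    n_per = np.full(len(targets), cfg.n_molecules, dtype=np.int64)
    chrom, start, length, _ = _place_molecules(cfg, targets, n_per, rng)
    n_mol = len(start)
    end = start + length - 1  # 1-based inclusive

    dm, dp, db = [], [], []

    # germline heterozygous/homozygous backbone alleles for this individual
    geno = truth.germline_genotypes.get(individual)
    if geno is not None:
        in_target = lambda s: any(
            t.chrom == s.chrom and t.start < s.pos <= t.end for t in targets
        )
        for s, g in zip(panel.backbone, geno):
            if g == 0 or not in_target(s):
                continue
            cid = cidx[s.chrom]
            cover = np.flatnonzero((chrom == cid) & (start <= s.pos) & (s.pos <= end))
            if len(cover) == 0:
                continue
            carrier = cover if g == 2 else cover[rng.random(len(cover)) < 0.5]
            dm.append(carrier)
            dp.append(np.full(len(carrier), s.pos, dtype=np.int64))
            db.append(np.full(len(carrier), s.alt, dtype=np.uint8))

    # somatic variants, phased pairs jointly
    variants = truth.somatic_variants
    paired = {i for i, j, _ in truth.phased_pairs} | {j for i, j, _ in truth.phased_pairs}
    cover_of = {}
    counts_rows = []
    carries: dict[int, np.ndarray] = {}
    for vi, v in enumerate(variants):
        cid = cidx[v.chrom]
        cover_of[vi] = np.flatnonzero((chrom == cid) & (start <= v.pos) & (v.pos <= end))
    for vi, v in enumerate(variants):
        if vi in paired:
            continue
        cover = cover_of[vi]
        carries[vi] = cover[rng.random(len(cover)) < v.vaf * tumour_fraction]
    for i, j, cis in truth.phased_pairs:
        vi, vj = variants[i], variants[j]
        ci, cj = cover_of[i], cover_of[j]
        both = np.intersect1d(ci, cj, assume_unique=True)
        only_i = np.setdiff1d(ci, both, assume_unique=True)
        only_j = np.setdiff1d(cj, both, assume_unique=True)
        p_clone = vi.vaf * tumour_fraction
        carrier_both = both[rng.random(len(both)) < p_clone]
        in_cis = rng.random(len(carrier_both)) < cis
        split_to_i = rng.random(len(carrier_both)) < 0.5
        gi = np.concatenate([
            carrier_both[in_cis],
            carrier_both[~in_cis & split_to_i],
            only_i[rng.random(len(only_i)) < p_clone],
        ])
        gj = np.concatenate([
            carrier_both[in_cis],
            carrier_both[~in_cis & ~split_to_i],
            only_j[rng.random(len(only_j)) < p_clone],
        ])
        carries[i] = np.unique(gi)
        carries[j] = np.unique(gj)
    for vi, v in enumerate(variants):
        carrier = carries.get(vi, np.zeros(0, dtype=np.int64))
        dm.append(carrier)
        dp.append(np.full(len(carrier), v.pos, dtype=np.int64))
        db.append(np.full(len(carrier), v.alt, dtype=np.uint8))
        counts_rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "alt": BASES[v.alt],
                "covering": len(cover_of[vi]),
                "alt_molecules": len(carrier),
            }
        )

    mol_diff_mol = np.concatenate(dm) if dm else np.zeros(0, dtype=np.int64)
    mol_diff_pos = np.concatenate(dp) if dp else np.zeros(0, dtype=np.int64)
    mol_diff_base = np.concatenate(db) if db else np.zeros(0, dtype=np.uint8)

    batch, fam, n_err, m_strand, m_umi = _emit_reads(
        cfg, rng, chrom, start, length, mol_diff_mol, mol_diff_pos, mol_diff_base
    )

    names = panel.contig_names
    mol_df = pd.DataFrame(
        {
            "molecule": np.arange(n_mol),
            "chrom": [names[c] for c in chrom],
            "start": start,
            "length": length,
            "strand": np.where(m_strand == 1, "-", "+"),
            "umi": m_umi,
            "family_size": fam,
        }
    )
    o = np.lexsort((mol_diff_pos, mol_diff_mol))
    allele_df = pd.DataFrame(
        {
            "molecule": mol_diff_mol[o],
            "chrom": [names[c] for c in chrom[mol_diff_mol[o]]],
            "pos": mol_diff_pos[o],
            "base": [BASES[b] for b in mol_diff_base[o]],
        }
    )
    struth = SampleTruth(
        molecules=mol_df,
        alleles=allele_df,
        variant_counts=pd.DataFrame(counts_rows),
        n_error_bases=n_err,
        total_bases=batch.total_bases,
    )
    return batch, struth


def simulate_dilution(
    cfg: SimConfig,
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    mix_fraction: float,
    n_sites: int,
    rng: np.random.Generator | None = None,
    window: int = 300,
) -> tuple[ReadBatch, pd.DataFrame]:
    """Two-individual admixture over discordant backbone SNPs.

    Reads derive from individual B with probability ``mix_fraction``;
    interrogated sites are those where A is hom-ref and B carries the alt
    (B-het sites have expected minor VAF ``mix_fraction/2``, B-hom sites
    ``mix_fraction``).  ``cfg.n_molecules`` molecules are drawn per site and
    every fragment covers its site.  Returns reads and a per-site truth
    table (genotype_b, expected VAF, true B-origin alt molecules).
    """
    if not 0.0 <= mix_fraction <= 0.5:
        raise ValueError("mix_fraction outside [0, 0.5]")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    panel = cfg.panel
    disc = np.flatnonzero((genotypes_a == 0) & (genotypes_b > 0))
    if len(disc) == 0:
        raise ValueError("no discordant backbone sites between the two individuals")
    if len(disc) < n_sites:
        raise ValueError(f"only {len(disc)} discordant sites available, need {n_sites}")
    sites = [panel.backbone[i] for i in disc[:n_sites]]
    gb = genotypes_b[disc[:n_sites]]

    n = cfg.n_molecules
    chroms, starts, lengths, site_of = [], [], [], []
    cidx = panel.contig_index
    for si, s in enumerate(sites):
        L = _truncnorm_lengths(cfg, window, n, rng)
        # place each fragment so it covers the interrogated SNP
        lo = np.maximum(s.pos - L + 1, 1)
        st = lo + rng.integers(0, np.minimum(L, s.pos - lo + 1))
        chroms.append(np.full(n, cidx[s.chrom], dtype=np.int16))
        starts.append(st)
        lengths.append(L)
        site_of.append(np.full(n, si, dtype=np.int32))
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts).astype(np.int64)
    length = np.concatenate(lengths)
    site_of = np.concatenate(site_of)
    n_mol = len(start)

    from_b = rng.random(n_mol) < mix_fraction
    # allele carried at the molecule's own site
    g_site = gb[site_of]
    carries_alt = from_b & (
        (g_site == 2) | ((g_site == 1) & (rng.random(n_mol) < 0.5))
    )
    alt_idx = np.flatnonzero(carries_alt)
    site_pos = np.array([s.pos for s in sites], dtype=np.int64)
    site_alt = np.array([s.alt for s in sites], dtype=np.uint8)
    mol_diff_mol = alt_idx
    mol_diff_pos = site_pos[site_of[alt_idx]]
    mol_diff_base = site_alt[site_of[alt_idx]]

    batch, fam, n_err, _, _ = _emit_reads(
        cfg, rng, chrom, start, length, mol_diff_mol, mol_diff_pos, mol_diff_base
    )

    exp_vaf = np.where(gb == 2, mix_fraction, mix_fraction / 2.0)
    truth = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [BASES[s.ref] for s in sites],
            "alt": [BASES[s.alt] for s in sites],
            "genotype_b": gb,
            "expected_vaf": exp_vaf,
            "true_alt_molecules": np.bincount(site_of[alt_idx], minlength=len(sites)),
            "molecules": n,
        }
    )
    return batch, truth


def simulate_cnv_sample(
    cfg: SimConfig,
    cnv_segments: list[CnvSegment],
    tumour_fraction: float,
    genotypes: np.ndarray,
    base_depth: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Backbone depth + allele counts under a segmental copy-number profile.

    Count-level model: expected relative depth at a locus inside a segment
    with ``copies`` total copies is ``(1 - tf) + tf * copies / 2``; at
    germline-het loci the alt-read fraction follows the allele-copy ratio
    (the affected haplotype is chosen at random per locus, so B-allele
    fractions split symmetrically around 0.5).
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction outside [0, 1]")
    ivs = sorted(cnv_segments, key=lambda s: (s.chrom, s.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError("CNV segments overlap")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    panel = cfg.panel
    tf = tumour_fraction

    rows = []
    for s, g in zip(panel.backbone, genotypes):
        copies = 2
        for seg in cnv_segments:
            if seg.chrom == s.chrom and seg.start <= s.pos <= seg.end:
                copies = seg.copies
                break
        rel = (1 - tf) + tf * copies / 2.0
        depth = int(rng.poisson(base_depth * rel))
        if g == 1:
            # alt allele sits on the affected haplotype with probability 1/2
            alt_t = 1 + (copies - 2) * int(rng.random() < 0.5) if copies >= 1 else 0
            denom = (1 - tf) * 2 + tf * copies
            frac = ((1 - tf) * 1 + tf * alt_t) / denom if denom > 0 else 0.0
        elif g == 2:
            frac = 1.0
        else:
            frac = 0.0
        alt = int(rng.binomial(depth, frac)) if depth else 0
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "genotype": int(g),
                "copies": copies,
                "depth": depth,
                "ref_count": depth - alt,
                "alt_count": alt,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical cohort simulator
# ---------------------------------------------------------------------------


@dataclass
class ClinicalSimSpec:
    """Cohort-level clinical simulation parameters.

    Hazards are exponential event rates per month; the defaults mirror the
    modelled disease setting (roughly half the cohort achieving an early
    molecular response, a large protective effect of EMR on progression,
    censoring at the study's potential follow-up horizon) and a log-normal
    baseline burden with median ≈ 530 hGE/mL and IQR ≈ 280–2070.
    """

    n_patients: int = 17
    emr_fraction: float = 8 / 17
    hazard_emr: float = 0.0037
    hazard_no_emr: float = 0.034
    censor_time: float = 50.0
    baseline_log10_mean: float = 2.725
    baseline_log10_sd: float = 0.644
    cmr_prob_emr: float = 0.95
    cmr_prob_no_emr: float = 0.125

    def __post_init__(self):
        if self.hazard_emr <= 0 or self.hazard_no_emr <= 0:
            raise ValueError("hazards must be > 0")
        if not 0.0 <= self.emr_fraction <= 1.0:
            raise ValueError("emr_fraction outside [0, 1]")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")


TIMEPOINTS = [("baseline", 0), ("early", 10), ("eot", 120), ("followup", 270)]


def simulate_cohort(
    spec: ClinicalSimSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a clinical cohort and per-patient longitudinal burdens.

    Returns (cohort table, burden series).  EMR patients drop >= 2 log10 in
    ctDNA burden by the early timepoint; progression times are exponential
    with the group hazard, censored at ``censor_time``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    emr = rng.random(n) < spec.emr_fraction
    base_log10 = rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd, n)
    baseline = 10.0**base_log10
    ldh = np.maximum(0.3, 0.9 * (base_log10 - 1.2) + rng.normal(0, 0.25, n))

    hazard = np.where(emr, spec.hazard_emr, spec.hazard_no_emr)
    t_event = rng.exponential(1.0 / hazard)
    pfs = np.minimum(t_event, spec.censor_time)
    pfs_event = t_event <= spec.censor_time
    extra = rng.exponential(12.0, n)
    t_os = np.where(pfs_event, t_event + extra, np.inf)
    os_t = np.minimum(t_os, spec.censor_time)
    os_event = t_os <= spec.censor_time

    cmr_p = np.where(emr, spec.cmr_prob_emr, spec.cmr_prob_no_emr)
    is_cmr = rng.random(n) < cmr_p
    resp = np.where(is_cmr, "CMR", rng.choice(["PR", "PD/ED"], n))
    resp = np.where(pfs_event & (pfs < 6) & ~is_cmr, "PD/ED", resp)

    mrd = np.where(
        pfs_event & (pfs < spec.censor_time * 0.8),
        np.where(rng.random(n) < 0.5, "positive", "negative"),
        "negative",
    )

    rows, series = [], []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        drop_early = 2.0 + abs(rng.normal(0.4, 0.4)) if emr[i] else rng.uniform(-0.3, 1.8)
        tp_burden = {
            "baseline": baseline[i],
            "early": baseline[i] * 10.0 ** (-drop_early),
            "eot": baseline[i] * 10.0 ** (-(drop_early + (1.5 if emr[i] else 0.3))),
            "followup": (
                baseline[i] * 10.0 ** (-rng.uniform(0.0, 1.0))
                if pfs_event[i]
                else 0.0
            ),
        }
        for tp, day in TIMEPOINTS:
            series.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "day": day,
                    "true_burden_hge_ml": tp_burden[tp],
                }
            )
        rows.append(
            {
                "patient_id": pid,
                "emr": bool(emr[i]),
                "mrd_status": mrd[i],
                "eot_response": resp[i],
                "pfs_months": round(float(pfs[i]), 3),
                "pfs_event": bool(pfs_event[i]),
                "os_months": round(float(os_t[i]), 3),
                "os_event": bool(os_event[i]),
                "baseline_hge_ml": round(float(baseline[i]), 2),
                "ldh_uln": round(float(ldh[i]), 3),
                "r_ipi": rng.choice(["good", "poor"], p=[0.35, 0.65]),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(series)
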