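import pytest

import ctdna_mrd as cm


@pytest.fixture(scope="session")
def panel():
    return cm.build_panel(seed=0)


@pytest.fixture(scope="session")
def small_panel():
    """Two-contig panel for fast read-level tests."""
    return cm.build_panel(
        seed=1, genes=["TP53", "MYD88", "CREBBP"], n_backbone=64,
        contigs=["chr17", "chr3"], contig_length=200_000,
    )


def variant_at(panel, target, offset, vaf, shift=1):
    """Somatic variant at ``target.start + offset`` (1-based) with given VAF."""
    pos = target.start + offset
    ref = panel.ref_base(target.chrom, pos)
    return cm.SomaticVariant(target.chrom, pos, ref, (ref + shift) % 4, vaf)


@pytest.fixture
def make_variant():
    return variant_at


def centre_coverage_fraction(cfg, target_length: int, mid0: int | None = None) -> float:
    """P(a uniformly placed fragment covers a given 0-based target offset)."""
    from scipy import stats

    lo, hi = cfg.fragment_min, min(cfg.fragment_max, target_length)
    a = (lo - cfg.fragment_mean) / cfg.fragment_sd
    b = (hi - cfg.fragment_mean) / cfg.fragment_sd
    dist = stats.truncnorm(a, b, loc=cfg.fragment_mean, scale=cfg.fragment_sd)
    m = target_length // 2 if mid0 is None else mid0
    num = den = 0.0
    for L in range(lo, hi + 1):
        w = dist.cdf(L + 0.5) - dist.cdf(L - 0.5)
        starts = target_length - L + 1
        cov = min(m, target_length - L) - max(0, m - L + 1) + 1
        num += w * max(cov, 0) / starts
        den += w
    return num / den
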