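"""Pileup, somatic calling, tracked genotyping and phasing, vs brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import ctdna_mrd as cm
from ctdna_mrd.consensus import ErrorModel
from ctdna_mrd.panel import BASES
from ctdna_mrd.variants import Pileup

from conftest import variant_at

import pandas as pd


def _toy_pileup(panel, chrom, s1, counts_by_pos):
    """Build a Pileup over [s1, s1+L-1] from {pos: {base_char: n}} overrides.

    Unlisted positions get 10 reference molecules.
    """
    L = max(counts_by_pos) - s1 + 1 if counts_by_pos else 10
    mat = np.zeros((L, 5), dtype=np.int64)
    ref = panel.ref_slice(chrom, s1, L)
    mat[np.arange(L), ref] = 10
    for pos, spec in counts_by_pos.items():
        off = pos - s1
        mat[off] = 0
        for b, n in spec.items():
            mat[off, BASES.index(b)] = n
    return Pileup(panel, [(chrom, s1, s1 + L - 1)], [mat])


def _cover_all(panel):
    cov = {
        (c, p) for t in panel.targets for c, p in
        ((t.chrom, q) for q in range(t.start + 1, t.end + 1))
    }
    return cm.GenotypeTable(vafs={}, covered=cov)


class TestPileup:
    def test_counts_match_handcrafted_molecules(self, small_panel, make_variant):
        t = small_panel.targets[0]
        truth = cm.TruthSet(somatic_variants=[make_variant(small_panel, t, 150, 0.3)])
        cfg = cm.SimConfig(panel=small_panel, seed=1, n_molecules=500,
                           per_base_error=0.0)
        batch, st = cm.simulate_sample(cfg, truth, 1.0,
                                       rng=np.random.default_rng(1), targets=[t])
        cons = cm.consensus_collapse(batch)
        pile = cm.build_pileup(cons, [t])
        v = truth.somatic_variants[0]
        c = pile.base_counts(v.chrom, v.pos)
        surviving = st.molecules[st.molecules["family_size"] >= 3]
        expected_cover = (
            (surviving["start"] <= v.pos)
            & (surviving["start"] + surviving["length"] - 1 >= v.pos)
        ).sum()
        assert c.sum() == expected_cover
        carriers = set(st.alleles[st.alleles["pos"] == v.pos]["molecule"])
        expected_alt = len(carriers & set(surviving["molecule"]))
        assert c[v.alt] == expected_alt

    def test_positions_outside_targets_skipped(self, small_panel):
        t = small_panel.targets[0]
        pile = _toy_pileup(small_panel, t.chrom, t.start + 1, {})
        assert not pile.contains(t.chrom, t.start + 5000)
        with pytest.raises(KeyError):
            pile.base_counts(t.chrom, t.start + 5000)


class TestCallSomatic:
    def _em(self, rate):
        return ErrorModel(rate=rate, n_sites=1, total_molecules=1, alt_molecules=0,
                          per_site=pd.DataFrame())

    def test_planted_one_percent_variant_called(self, small_panel):
        # VAF 1% at 5000 informative molecules vs background 2.5e-4:
        # the binomial tail is astronomically small, Bonferroni cannot save it
        t = small_panel.targets[0]
        pos = t.start + 100
        ref = BASES[small_panel.ref_base(t.chrom, pos)]
        alt = "A" if ref != "A" else "C"
        pile = _toy_pileup(small_panel, t.chrom, pos, {pos: {ref: 4950, alt: 50}})
        calls = cm.call_somatic(pile, _cover_all(small_panel), self._em(2.5e-4),
                                alpha=0.05, n_tests=150_000)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.alt, c.status) == (pos, alt, "somatic")
        assert c.p_value < 0.05 / 150_000
        assert stats.binom.sf(49, 5000, 2.5e-4) == pytest.approx(c.p_value)

    def test_zero_alt_molecules_never_called(self, small_panel):
        t = small_panel.targets[0]
        pile = _toy_pileup(small_panel, t.chrom, t.start + 1, {})
        assert cm.call_somatic(pile, _cover_all(small_panel), self._em(1e-4)) == []

    def test_buccal_het_flagged_germline(self, small_panel):
        t = small_panel.targets[0]
        pos = t.start + 100
        ref = BASES[small_panel.ref_base(t.chrom, pos)]
        alt = "A" if ref != "A" else "C"
        pile = _toy_pileup(small_panel, t.chrom, pos, {pos: {ref: 500, alt: 450}})
        gt = cm.GenotypeTable(vafs={(t.chrom, pos, alt): 0.45},
                              covered={(t.chrom, pos)})
        calls = cm.call_somatic(pile, gt, self._em(1e-4), n_tests=100)
        assert [c.status for c in calls] == ["germline"]

    def test_missing_buccal_coverage_flagged_unevaluable(self, small_panel):
        t = small_panel.targets[0]
        pos = t.start + 100
        ref = BASES[small_panel.ref_base(t.chrom, pos)]
        alt = "A" if ref != "A" else "C"
        pile = _toy_pileup(small_panel, t.chrom, pos, {pos: {ref: 4000, alt: 400}})
        gt = cm.GenotypeTable(vafs={}, covered=set())
        with pytest.warns(UserWarning, match="germline-unevaluable"):
            calls = cm.call_somatic(pile, gt, self._em(1e-4), n_tests=100)
        assert [c.status for c in calls] == ["germline-unevaluable"]

    def test_higher_background_never_increases_calls(self, small_panel):
        t = small_panel.targets[0]
        pos = t.start + 100
        ref = BASES[small_panel.ref_base(t.chrom, pos)]
        alt = "A" if ref != "A" else "C"
        pile = _toy_pileup(small_panel, t.chrom, pos, {pos: {ref: 4993, alt: 7}})
        n_prev = None
        for rate in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2):
            n = len(cm.call_somatic(pile, _cover_all(small_panel),
                                    self._em(rate), n_tests=1000))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_no_false_calls_on_variant_free_replicates(self, small_panel):
        # family-wise alpha 0.05: expect a clean call set in >= 95% of runs
        t = small_panel.targets[0]
        false_runs = 0
        for seed in range(30):
            cfg = cm.SimConfig(panel=small_panel, seed=seed, n_molecules=1500)
            batch, _ = cm.simulate_sample(cfg, cm.TruthSet(), 0.0,
                                          rng=np.random.default_rng(100 + seed),
                                          targets=[t])
            cons = cm.consensus_collapse(batch)
            pile = cm.build_pileup(cons, [t])
            em = self._em(2.5e-6)
            calls = cm.call_somatic(pile, _cover_all(small_panel), em)
            false_runs += bool([c for c in calls if c.status == "somatic"])
        assert false_runs <= 3


class TestGenotypeTracked:
    def test_zero_alt_is_vaf_zero_not_missing(self, small_panel):
        t = small_panel.targets[0]
        pos = t.start + 100
        ref = BASES[small_panel.ref_base(t.chrom, pos)]
        alt = "A" if ref != "A" else "C"
        pile = _toy_pileup(small_panel, t.chrom, pos, {pos: {ref: 4000}})
        df = cm.genotype_tracked(pile, [(t.chrom, pos, ref, alt)])
        row = df.iloc[0]
        assert row["vaf"] == 0.0 and not row["missing"]
        assert row["informative_molecules"] == 4000

    def test_uncovered_site_is_missing(self, small_panel):
        t = small_panel.targets[0]
        pile = _toy_pileup(small_panel, t.chrom, t.start + 1, {})
        df = cm.genotype_tracked(pile, [("chr3", 50, "A", "C")])
        assert df.iloc[0]["missing"] and np.isnan(df.iloc[0]["vaf"])

    def test_empty_tracked_list_rejected(self, small_panel):
        t = small_panel.targets[0]
        pile = _toy_pileup(small_panel, t.chrom, t.start + 1, {})
        with pytest.raises(ValueError):
            cm.genotype_tracked(pile, [])

    def test_decay_series_slope_recovered(self, small_panel, make_variant):
        # VAF halves per timepoint; log2 regression slope should be ~ -1
        t = small_panel.targets[0]
        v = make_variant(small_panel, t, 150, 0.4)
        truth = cm.TruthSet(somatic_variants=[v])
        vafs = []
        for k, tf in enumerate([1.0, 0.5, 0.25, 0.125]):
            cfg = cm.SimConfig(panel=small_panel, seed=40 + k, n_molecules=4000)
            batch, _ = cm.simulate_sample(cfg, truth, tf,
                                          rng=np.random.default_rng(40 + k),
                                          targets=[t])
            pile = cm.build_pileup(cm.consensus_collapse(batch), [t])
            df = cm.genotype_tracked(pile, [(v.chrom, v.pos, BASES[v.ref], BASES[v.alt])])
            vafs.append(df.iloc[0]["vaf"])
        slope = np.polyfit(np.arange(4), np.log2(vafs), 1)[0]
        assert abs(slope + 1.0) < 0.15


class TestPhasedPairs:
    def _brute_force(self, cons, variants, max_distance=100):
        """Exhaustive per-molecule check on explicit consensus sequences."""
        mols = cons.to_explicit()
        out = {}
        for i in range(len(variants)):
            for j in range(i + 1, len(variants)):
                (ca, pa, _, aa), (cb, pb, _, ab) = variants[i], variants[j]
                if ca != cb or abs(pa - pb) > max_distance:
                    continue
                support = cover = 0
                for m in mols:
                    if m.chrom == ca and m.start <= min(pa, pb) and m.end >= max(pa, pb):
                        cover += 1
                        if (
                            m.base_at(pa) == BASES.index(aa)
                            and m.base_at(pb) == BASES.index(ab)
                        ):
                            support += 1
                out[(pa, pb)] = (support, cover)
        return out

    def test_planted_cis_pairs_recovered_and_match_oracle(self, small_panel):
        t = small_panel.targets[0]
        v1 = variant_at(small_panel, t, 120, 0.05)
        v2 = variant_at(small_panel, t, 180, 0.05)  # 60 bp apart
        v3 = variant_at(small_panel, t, 282, 0.05)  # 102 bp from v2
        truth = cm.TruthSet(somatic_variants=[v1, v2, v3],
                            phased_pairs=[(0, 1, 1.0)])
        cfg = cm.SimConfig(panel=small_panel, seed=9, n_molecules=900)
        batch, _ = cm.simulate_sample(cfg, truth, 1.0,
                                      rng=np.random.default_rng(9), targets=[t])
        cons = cm.consensus_collapse(batch)
        variants = [
            (v.chrom, v.pos, BASES[v.ref], BASES[v.alt]) for v in (v1, v2, v3)
        ]
        pairs = cm.detect_phased_pairs(cons, variants)
        oracle = self._brute_force(cons, variants)
        # pair beyond 100 bp is never evaluated
        assert (v2.pos, v3.pos) not in {(p.pos_a, p.pos_b) for p in pairs}
        got = {(p.pos_a, p.pos_b): (p.support, p.covering) for p in pairs}
        expected = {k: v for k, v in oracle.items() if v[0] >= 1}
        assert got == expected
        # the planted cis pair is recovered with solid support
        assert got[(v1.pos, v2.pos)][0] >= 10

    def test_support_bounded_by_individual_alt_counts(self, small_panel):
        t = small_panel.targets[0]
        v1 = variant_at(small_panel, t, 140, 0.1)
        v2 = variant_at(small_panel, t, 160, 0.1)
        truth = cm.TruthSet(somatic_variants=[v1, v2], phased_pairs=[(0, 1, 1.0)])
        cfg = cm.SimConfig(panel=small_panel, seed=10, n_molecules=600)
        batch, _ = cm.simulate_sample(cfg, truth, 1.0,
                                      rng=np.random.default_rng(10), targets=[t])
        cons = cm.consensus_collapse(batch)
        pile = cm.build_pileup(cons, [t])
        pairs = cm.detect_phased_pairs(
            cons, [(v.chrom, v.pos, BASES[v.ref], BASES[v.alt]) for v in (v1, v2)]
        )
        assert len(pairs) == 1
        alt_counts = [pile.base_counts(v.chrom, v.pos)[v.alt] for v in (v1, v2)]
        assert pairs[0].support <= min(alt_counts)

    def test_trans_variants_yield_no_pair(self, small_panel):
        t = small_panel.targets[0]
        v1 = variant_at(small_panel, t, 140, 0.3)
        v2 = variant_at(small_panel, t, 160, 0.3)
        truth = cm.TruthSet(somatic_variants=[v1, v2], phased_pairs=[(0, 1, 0.0)])
        cfg = cm.SimConfig(panel=small_panel, seed=11, n_molecules=400,
                           per_base_error=0.0)
        batch, _ = cm.simulate_sample(cfg, truth, 1.0,
                                      rng=np.random.default_rng(11), targets=[t])
        cons = cm.consensus_collapse(batch)
        pairs = cm.detect_phased_pairs(
            cons, [(v.chrom, v.pos, BASES[v.ref], BASES[v.alt]) for v in (v1, v2)]
        )
        assert pairs == []


class TestCompareVariantSets:
    def test_identical_sets_fully_concordant(self, small_panel):
        t = small_panel.targets[0]
        calls = [(t.chrom, t.start + k, "A", "C") for k in range(1, 11)]
        res = cm.compare_variant_sets(calls, calls, [t])
        assert res == {"shared": 10, "plasma_only": 0, "tissue_only": 0,
                       "concordance": 1.0}

    def test_disjoint_sets_share_nothing(self, small_panel):
        t = small_panel.targets[0]
        a = [(t.chrom, t.start + 1, "A", "C")]
        b = [(t.chrom, t.start + 2, "A", "C")]
        res = cm.compare_variant_sets(a, b, [t])
        assert res["shared"] == 0 and res["concordance"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_subsets_match_set_algebra(self, small_panel, seed):
        rng = np.random.default_rng(seed)
        t = small_panel.targets[0]
        universe = [(t.chrom, t.start + k, "A", "C") for k in range(1, 60)]
        plasma = [v for v in universe if rng.random() < 0.6]
        tissue = [v for v in universe if rng.random() < 0.6]
        res = cm.compare_variant_sets(plasma, tissue, [t])
        sp, st_ = set(plasma), set(tissue)
        assert res["shared"] == len(sp & st_)
        assert res["plasma_only"] == len(sp - st_)
        assert res["tissue_only"] == len(st_ - sp)
        # off-panel variants are ignored entirely
        off = [("chr3", 5, "A", "C")]
        res2 = cm.compare_variant_sets(plasma + off, tissue + off, [t])
        assert res2 == res
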