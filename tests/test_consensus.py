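"""UMI family grouping and consensus voting, checked against brute force."""

import numpy as np
import pytest

import ctdna_mrd as cm
from ctdna_mrd.consensus import ConsensusSet
from ctdna_mrd.reads import ReadRecord, batch_from_records

from conftest import variant_at


def _read(panel, chrom, start, umi, seq=None, length=12, strand="+", name="r"):
    if seq is None:
        seq = "".join("ACGTN"[b] for b in panel.ref_slice(chrom, start, length))
    return ReadRecord(name=name, chrom=chrom, start=start, strand=strand,
                      seq=seq, umi=umi)


class TestGrouping:
    def test_identical_key_reads_form_one_family(self, small_panel):
        reads = [_read(small_panel, "chr17", 1000, "A" * 10, name=f"r{i}")
                 for i in range(5)]
        fams = cm.group_umi_families(reads)
        assert len(fams) == 1 and fams[0].size == 5

    def test_hamming_one_umis_split_or_merge_by_tolerance(self, small_panel):
        reads = [_read(small_panel, "chr17", 1000, "A" * 10, name=f"a{i}")
                 for i in range(4)]
        reads.append(_read(small_panel, "chr17", 1000, "A" * 9 + "T", name="b"))
        by_size = sorted(f.size for f in cm.group_umi_families(reads, 0))
        assert by_size == [1, 4]
        fams = cm.group_umi_families(reads, 1)
        assert len(fams) == 1 and fams[0].size == 5

    def test_directional_rule_keeps_balanced_families_apart(self, small_panel):
        reads = [_read(small_panel, "chr17", 1000, "A" * 10, name=f"a{i}")
                 for i in range(4)]
        reads += [_read(small_panel, "chr17", 1000, "A" * 9 + "T", name=f"b{i}")
                  for i in range(4)]
        # 4 vs 4: size_small (4) > size_large/2 + 1 (3) -> no merge
        assert len(cm.group_umi_families(reads, 1)) == 2

    def test_differing_position_or_strand_split_families(self, small_panel):
        reads = [
            _read(small_panel, "chr17", 1000, "A" * 10),
            _read(small_panel, "chr17", 1001, "A" * 10),
            _read(small_panel, "chr17", 1000, "A" * 10, strand="-"),
        ]
        assert len(cm.group_umi_families(reads)) == 3

    def test_bad_umi_length_excluded_with_warning(self, small_panel):
        reads = [_read(small_panel, "chr17", 1000, "A" * 10)]
        bad = ReadRecord("x", "chr17", 1000, "+", "ACGT", "AAAA")
        with pytest.warns(UserWarning, match="UMI length"):
            fams = cm.group_umi_families(reads + [bad])
        assert sum(f.size for f in fams) == 1

    def test_simulated_partition_matches_generator_truth(self, small_panel):
        cfg = cm.SimConfig(panel=small_panel, seed=3, n_molecules=300,
                           per_base_error=0.0)
        batch, st = cm.simulate_sample(
            cfg, cm.TruthSet(), 0.0, rng=np.random.default_rng(3),
            targets=small_panel.targets[:1],
        )
        fams = cm.group_umi_families(batch.to_records())
        truth_sizes = sorted(st.molecules["family_size"])
        got_sizes = sorted(f.size for f in fams)
        # UMI collisions are possible but vanishingly rare at this scale
        assert got_sizes == truth_sizes


class TestCollapse:
    def _family(self, small_panel, seqs, start=1000):
        reads = [_read(small_panel, "chr17", start, "C" * 10, seq=s, name=f"r{i}")
                 for i, s in enumerate(seqs)]
        return cm.group_umi_families(reads)

    def test_family_below_min_size_dropped(self, small_panel):
        ref = "".join("ACGTN"[b] for b in small_panel.ref_slice("chr17", 1000, 12))
        fams = self._family(small_panel, [ref, ref])
        assert cm.collapse_families(fams, min_family=3) == []
        assert len(cm.collapse_families(fams, min_family=2)) == 1

    def test_four_of_five_majority_wins(self, small_panel):
        ref = "".join("ACGTN"[b] for b in small_panel.ref_slice("chr17", 1000, 12))
        alt = ("T" if ref[5] != "T" else "G")
        discordant = ref[:5] + alt + ref[6:]
        fams = self._family(small_panel, [ref] * 4 + [discordant])
        (mol,) = cm.collapse_families(fams)
        assert "".join("ACGTN"[b] for b in mol.seq) == ref  # 4/5 >= 2/3

    def test_two_two_split_masks_to_n(self, small_panel):
        ref = "".join("ACGTN"[b] for b in small_panel.ref_slice("chr17", 1000, 12))
        alt = ("T" if ref[5] != "T" else "G")
        discordant = ref[:5] + alt + ref[6:]
        fams = self._family(small_panel, [ref, ref, discordant, discordant])
        (mol,) = cm.collapse_families(fams)
        assert mol.seq[5] == 4  # N
        assert mol.base_at(1005) == 4

    def test_three_of_four_fails_two_thirds_on_minority(self, small_panel):
        ref = "".join("ACGTN"[b] for b in small_panel.ref_slice("chr17", 1000, 12))
        alt = ("T" if ref[5] != "T" else "G")
        discordant = ref[:5] + alt + ref[6:]
        fams = self._family(small_panel, [ref] * 3 + [discordant])
        (mol,) = cm.collapse_families(fams)
        assert mol.seq[5] == small_panel.ref_base("chr17", 1005)  # 3/4 >= 2/3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_engine_equals_explicit_path(self, small_panel, seed):
        t = small_panel.targets[0]
        truth = cm.TruthSet(somatic_variants=[variant_at(small_panel, t, 150, 0.3)])
        cfg = cm.SimConfig(panel=small_panel, seed=seed, n_molecules=30,
                           per_base_error=0.02)
        batch, _ = cm.simulate_sample(cfg, truth, 1.0,
                                      rng=np.random.default_rng(seed), targets=[t])
        engine = {
            (m.chrom, m.start, m.strand, tuple(m.seq))
            for m in cm.consensus_collapse(batch).to_explicit()
        }
        explicit = {
            (m.chrom, m.start, m.strand, tuple(m.seq))
            for m in cm.collapse_families(cm.group_umi_families(batch.to_records()))
        }
        assert engine == explicit

    def test_engine_equals_explicit_with_ragged_extents(self, small_panel):
        # same start+UMI but different fragment lengths (a UMI collision)
        ref20 = "".join("ACGTN"[b] for b in small_panel.ref_slice("chr17", 1000, 20))
        reads = [
            _read(small_panel, "chr17", 1000, "G" * 10, seq=ref20, name="a"),
            _read(small_panel, "chr17", 1000, "G" * 10, seq=ref20, name="b"),
            _read(small_panel, "chr17", 1000, "G" * 10, seq=ref20[:10], name="c"),
        ]
        batch = batch_from_records(reads, small_panel)
        engine = cm.consensus_collapse(batch, min_family=3).to_explicit()
        explicit = cm.collapse_families(cm.group_umi_families(reads), min_family=3)
        assert len(engine) == len(explicit) == 1
        assert np.array_equal(engine[0].seq, explicit[0].seq)
        assert len(engine[0].seq) == 20

    def test_error_free_consensus_equals_truth(self, small_panel):
        t = small_panel.targets[1]
        truth = cm.TruthSet(somatic_variants=[variant_at(small_panel, t, 150, 0.4)])
        cfg = cm.SimConfig(panel=small_panel, seed=5, n_molecules=400,
                           per_base_error=0.0)
        batch, st = cm.simulate_sample(cfg, truth, 1.0,
                                       rng=np.random.default_rng(5), targets=[t])
        cons = cm.consensus_collapse(batch)
        assert cons.n_molecules == (st.molecules["family_size"] >= 3).sum()
        # consensus diffs = alleles of surviving molecules, no Ns
        surviving = set(st.molecules[st.molecules["family_size"] >= 3]["molecule"])
        truth_diffs = {
            (int(p)) for m, p in zip(st.alleles["molecule"], st.alleles["pos"])
            if int(m) in surviving
        }
        got = {int(p) for p in cons.diff_pos}
        assert got == truth_diffs
        assert not (cons.diff_base == 4).any()


class TestErrorModel:
    def _toy_consensus(self, small_panel, n_mol, alt_events):
        """n_mol molecules covering chr17:901-1300; alt_events = [(pos, base)]."""
        start = np.full(n_mol, 901, dtype=np.int64)
        length = np.full(n_mol, 400, dtype=np.int64)
        dm = np.array([i for i, _ in enumerate(alt_events)], dtype=np.int64)
        dp = np.array([p for p, _ in alt_events], dtype=np.int64)
        db = np.array([b for _, b in alt_events], dtype=np.uint8)
        o = np.lexsort((dp, dm))
        return ConsensusSet(
            panel=small_panel,
            chrom=np.zeros(n_mol, dtype=np.int16),
            start=start, length=length,
            strand=np.zeros(n_mol, dtype=np.int8),
            umi=np.arange(n_mol, dtype=np.uint32),
            family_size=np.full(n_mol, 3, dtype=np.int64),
            diff_mol=dm[o], diff_pos=dp[o], diff_base=db[o],
        )

    def test_zero_alts_floored_at_half_count(self, small_panel):
        cons = self._toy_consensus(small_panel, 4000, [])
        sites = [("chr17", 1000 + k) for k in range(202)]
        em = cm.estimate_background_error(cons, sites)
        assert em.total_molecules == 202 * 4000
        assert em.alt_molecules == 0
        assert em.rate == pytest.approx(0.5 / 808000)

    def test_single_site_rate_is_simple_division(self, small_panel):
        ref = small_panel.ref_base("chr17", 1000)
        alt = (ref + 1) % 4
        cons = self._toy_consensus(small_panel, 8000, [(1000, alt), (1000, alt)])
        em = cm.estimate_background_error(cons, [("chr17", 1000)])
        assert em.rate == pytest.approx(2 / 8000)
        assert em.per_site.iloc[0]["rate"] == pytest.approx(2.5e-4)

    def test_germline_sites_excluded_with_warning(self, small_panel):
        cons = self._toy_consensus(small_panel, 100, [])
        sites = [("chr17", 1000), ("chr17", 1001)]
        with pytest.warns(UserWarning, match="germline"):
            em = cm.estimate_background_error(cons, sites, {("chr17", 1001)})
        assert em.n_sites == 1

    def test_suppression_monotone_in_min_family(self, small_panel):
        cfg = cm.SimConfig(panel=small_panel, seed=11, n_molecules=4000,
                           per_base_error=0.01)
        batch, _ = cm.simulate_sample(cfg, cm.TruthSet(), 0.0,
                                      rng=np.random.default_rng(11),
                                      targets=small_panel.targets[:1])
        t = small_panel.targets[0]
        sites = [(t.chrom, t.start + off) for off in (40, 90, 140, 190, 240)]
        rates = {}
        for mf in (3, 5):
            cons = cm.consensus_collapse(batch, min_family=mf)
            rates[mf] = cm.estimate_background_error(cons, sites).rate
        assert rates[5] <= rates[3] * 1.5 + 1e-6
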