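"""Generator bookkeeping: emitted reads must reconcile with sidecar truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctdna_mrd as cm
from ctdna_mrd.simulate import surviving_family_fraction

from conftest import variant_at


def _sample(panel, truth, tf, *, seed=0, n_molecules=500, targets=None, **kw):
    cfg = cm.SimConfig(panel=panel, seed=seed, n_molecules=n_molecules, **kw)
    return cm.simulate_sample(
        cfg, truth, tf, rng=np.random.default_rng(seed),
        targets=targets or panel.targets[:2],
    )


class TestSimulateSample:
    def test_family_sizes_reconcile_with_read_count(self, small_panel):
        batch, st = _sample(small_panel, cm.TruthSet(), 0.0, seed=11)
        assert st.molecules["family_size"].sum() == batch.n_reads

    def test_zero_tumour_fraction_emits_no_somatic_alleles(self, small_panel):
        t = small_panel.targets[0]
        truth = cm.TruthSet(somatic_variants=[variant_at(small_panel, t, 150, 0.5)])
        batch, st = _sample(small_panel, truth, 0.0, seed=2, targets=[t])
        assert st.variant_counts["alt_molecules"].sum() == 0

    def test_raw_alt_fraction_within_binomial_ci_of_vaf(self, small_panel):
        t = small_panel.targets[0]
        truth = cm.TruthSet(somatic_variants=[variant_at(small_panel, t, 150, 0.5)])
        batch, st = _sample(
            small_panel, truth, 1.0, seed=3, n_molecules=1000,
            per_base_error=0.0, targets=[t],
        )
        row = st.variant_counts.iloc[0]
        ci = stats.binomtest(int(row["alt_molecules"]), int(row["covering"])).proportion_ci(0.95)
        assert ci.low <= 0.5 <= ci.high

    def test_error_free_reads_match_molecule_alleles_exactly(self, small_panel):
        t = small_panel.targets[0]
        truth = cm.TruthSet(somatic_variants=[variant_at(small_panel, t, 150, 0.3)])
        batch, st = _sample(
            small_panel, truth, 1.0, seed=4, per_base_error=0.0, targets=[t]
        )
        assert st.n_error_bases == 0
        # with no sequencing error, read diffs are exactly the expanded
        # molecule alleles: every read of a carrier shows the alt, no other
        # read deviates from reference
        mol_alleles = {
            (int(m), int(p)) for m, p in zip(st.alleles["molecule"], st.alleles["pos"])
        }
        read_diffs = {
            (int(batch.molecule[r]), int(p))
            for r, p in zip(batch.diff_read, batch.diff_pos)
        }
        assert read_diffs == mol_alleles
        fam = st.molecules.set_index("molecule")["family_size"]
        n_expected = sum(fam[m] for m, _ in mol_alleles)
        assert len(batch.diff_read) == n_expected

    def test_empirical_mismatch_rate_within_3_se(self, small_panel):
        batch, st = _sample(
            small_panel, cm.TruthSet(), 0.0, seed=5, n_molecules=2000,
            per_base_error=0.003,
        )
        se = np.sqrt(0.003 * 0.997 / st.total_bases)
        assert abs(st.raw_error_rate - 0.003) < 3 * se

    def test_family_size_mean_within_3_se(self, small_panel):
        cfg = cm.SimConfig(panel=small_panel, seed=6, n_molecules=2000)
        batch, st = cm.simulate_sample(
            cfg, cm.TruthSet(), 0.0, rng=np.random.default_rng(6),
            targets=small_panel.targets[:1],
        )
        fam = st.molecules["family_size"]
        r, mean = cfg.family_dispersion, cfg.family_mean
        var = r * (1 - r / (r + mean - 1)) / (r / (r + mean - 1)) ** 2
        assert abs(fam.mean() - mean) < 3 * np.sqrt(var / len(fam))

    def test_all_coordinates_inside_targets(self, small_panel):
        targets = small_panel.targets[:2]
        batch, _ = _sample(small_panel, cm.TruthSet(), 0.0, seed=7, targets=targets)
        names = small_panel.contig_names
        for t in targets:
            cid = small_panel.contig_index[t.chrom]
            m = batch.chrom == cid
            in_t = (batch.start[m] >= t.start + 1) & (
                batch.start[m] + batch.length[m] - 1 <= t.end
            )
            assert in_t.all()
        assert set(names[c] for c in batch.chrom) <= {t.chrom for t in targets}

    def test_phased_pair_cooccurs_on_molecules(self, small_panel):
        t = small_panel.targets[0]
        v1 = variant_at(small_panel, t, 130, 0.3)
        v2 = variant_at(small_panel, t, 170, 0.3)
        truth = cm.TruthSet(somatic_variants=[v1, v2], phased_pairs=[(0, 1, 1.0)])
        batch, st = _sample(
            small_panel, truth, 1.0, seed=8, per_base_error=0.0, targets=[t]
        )
        per_mol = st.alleles.groupby("molecule")["pos"].apply(set)
        both = {v1.pos, v2.pos}
        # any molecule covering both positions carries both alts or neither
        mols = st.molecules.set_index("molecule")
        for mol, alleles in per_mol.items():
            s = mols.loc[mol, "start"]
            e = s + mols.loc[mol, "length"] - 1
            if s <= v1.pos and e >= v2.pos:
                assert alleles & both in (both, set())

    def test_vaf_sum_above_one_rejected(self, small_panel):
        t = small_panel.targets[0]
        vs = [variant_at(small_panel, t, 150, 0.6, shift=1),
              variant_at(small_panel, t, 150, 0.6, shift=2)]
        with pytest.raises(ValueError, match="VAF sum"):
            _sample(small_panel, cm.TruthSet(somatic_variants=vs), 1.0)

    def test_distant_phased_pair_rejected(self, small_panel):
        t = small_panel.targets[0]
        vs = [variant_at(small_panel, t, 50, 0.3), variant_at(small_panel, t, 250, 0.3)]
        truth = cm.TruthSet(somatic_variants=vs, phased_pairs=[(0, 1, 1.0)])
        with pytest.raises(ValueError, match="100"):
            _sample(small_panel, truth, 1.0)

    @pytest.mark.parametrize("bad", [
        dict(per_base_error=1.5), dict(n_molecules=0), dict(umi_length=8),
        dict(fragment_min=0), dict(family_mean=0.5),
    ])
    def test_config_validation(self, small_panel, bad):
        with pytest.raises(ValueError):
            cm.SimConfig(panel=small_panel, **bad)


class TestSimulateDilution:
    def _genotypes(self, panel, seed):
        rng = np.random.default_rng(seed)
        return cm.draw_genotypes(panel, rng), cm.draw_genotypes(panel, rng)

    def test_zero_mix_has_no_true_minor_molecules(self, small_panel):
        ga, gb = self._genotypes(small_panel, 1)
        cfg = cm.SimConfig(panel=small_panel, seed=1, n_molecules=200)
        _, truth = cm.simulate_dilution(cfg, ga, gb, 0.0, 10)
        assert truth["true_alt_molecules"].sum() == 0

    def test_hom_alt_site_expected_vaf_equals_mix(self, small_panel):
        ga, gb = self._genotypes(small_panel, 1)
        cfg = cm.SimConfig(panel=small_panel, seed=2, n_molecules=200)
        _, truth = cm.simulate_dilution(cfg, ga, gb, 0.5, 10)
        hom = truth[truth["genotype_b"] == 2]
        het = truth[truth["genotype_b"] == 1]
        assert (hom["expected_vaf"] == 0.5).all()
        assert (het["expected_vaf"] == 0.25).all()

    def test_true_alt_counts_match_expectation(self, small_panel):
        ga, gb = self._genotypes(small_panel, 3)
        cfg = cm.SimConfig(panel=small_panel, seed=3, n_molecules=3000)
        _, truth = cm.simulate_dilution(cfg, ga, gb, 0.05, 12)
        expected = (truth["expected_vaf"] * truth["molecules"]).sum()
        observed = truth["true_alt_molecules"].sum()
        sd = np.sqrt((truth["expected_vaf"] * (1 - truth["expected_vaf"])
                      * truth["molecules"]).sum())
        assert abs(observed - expected) < 4 * sd

    def test_no_discordant_sites_errors(self, small_panel):
        g = cm.draw_genotypes(small_panel, np.random.default_rng(4))
        cfg = cm.SimConfig(panel=small_panel, seed=4, n_molecules=10)
        with pytest.raises(ValueError, match="discordant"):
            cm.simulate_dilution(cfg, g, g.copy(), 0.1, 5)


class TestSimulateCnv:
    def test_neutral_profile_has_unit_relative_depth(self, panel):
        cfg = cm.SimConfig(panel=panel, seed=5)
        g = cm.draw_genotypes(panel, np.random.default_rng(5))
        tab = cm.simulate_cnv_sample(cfg, [], 0.0, g, base_depth=500,
                                     rng=np.random.default_rng(5))
        assert abs(tab["depth"].mean() / 500 - 1.0) < 0.02

    def test_single_copy_loss_at_full_tumour_fraction(self, panel):
        cfg = cm.SimConfig(panel=panel, seed=6)
        g = cm.draw_genotypes(panel, np.random.default_rng(6))
        arm = panel.arms.iloc[0]
        seg = cm.CnvSegment(arm["chrom"], int(arm["start"]) + 1, int(arm["end"]), 1)
        tab = cm.simulate_cnv_sample(cfg, [seg], 1.0, g, base_depth=2000,
                                     rng=np.random.default_rng(6))
        inside = tab[tab["copies"] == 1]
        ratio = inside["depth"].mean() / 2000
        assert abs(ratio - 0.5) < 0.02
        assert abs(np.log2(ratio) - (-1.0)) < 0.06
        # LOH: het alt fraction collapses to 0 or 1
        het = inside[inside["genotype"] == 1]
        baf = het["alt_count"] / het["depth"]
        assert ((baf < 0.05) | (baf > 0.95)).all()

    def test_het_minor_fraction_one_third_at_half_tumour_fraction(self, panel):
        cfg = cm.SimConfig(panel=panel, seed=7)
        g = np.ones(len(panel.backbone), dtype=np.int8)  # all het
        arm = panel.arms.iloc[0]
        seg = cm.CnvSegment(arm["chrom"], int(arm["start"]) + 1, int(arm["end"]), 1)
        tab = cm.simulate_cnv_sample(cfg, [seg], 0.5, g, base_depth=4000,
                                     rng=np.random.default_rng(7))
        het = tab[tab["copies"] == 1]
        baf = het["alt_count"] / het["depth"]
        minor = np.minimum(baf, 1 - baf)
        assert abs(minor.mean() - 1 / 3) < 0.02

    def test_overlapping_segments_rejected(self, panel):
        cfg = cm.SimConfig(panel=panel, seed=8)
        g = cm.draw_genotypes(panel, np.random.default_rng(8))
        segs = [cm.CnvSegment("chr1", 1, 1000, 1), cm.CnvSegment("chr1", 500, 2000, 3)]
        with pytest.raises(ValueError, match="overlap"):
            cm.simulate_cnv_sample(cfg, segs, 0.5, g)


class TestSimulateCohort:
    def test_censoring_bound_and_emr_drop(self):
        spec = cm.ClinicalSimSpec(n_patients=200)
        cohort, series = cm.simulate_cohort(spec, seed=1)
        assert (cohort["pfs_months"] <= spec.censor_time).all()
        assert (cohort["os_months"] <= spec.censor_time).all()
        wide = series.pivot(index="patient_id", columns="timepoint",
                            values="true_burden_hge_ml")
        emr_ids = cohort[cohort["emr"]]["patient_id"]
        drop = np.log10(wide.loc[emr_ids, "baseline"] / wide.loc[emr_ids, "early"])
        assert (drop >= 2.0).all()

    def test_roundtrips_through_cohort_reader(self, tmp_path):
        cohort, _ = cm.simulate_cohort(cm.ClinicalSimSpec(n_patients=30), seed=2)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path, index=False)
        back = cm.outcomes.read_cohort_csv(path)
        pd.testing.assert_frame_equal(back, cohort, check_dtype=False)

    def test_large_cohort_recovers_designed_hazard_ratio(self):
        spec = cm.ClinicalSimSpec(n_patients=2000, hazard_emr=0.0034,
                                  hazard_no_emr=0.034)
        cohort, _ = cm.simulate_cohort(spec, seed=3)
        g, h = cohort[cohort["emr"]], cohort[~cohort["emr"]]
        hr, _ = cm.mh_hazard_ratio(g["pfs_months"], g["pfs_event"],
                                   h["pfs_months"], h["pfs_event"])
        assert 0.08 <= hr <= 0.125

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            cm.ClinicalSimSpec(hazard_emr=0.0)


def test_surviving_family_fraction_matches_empirical(small_panel):
    cfg = cm.SimConfig(panel=small_panel, seed=9, n_molecules=5000)
    _, st = cm.simulate_sample(
        cfg, cm.TruthSet(), 0.0, rng=np.random.default_rng(9),
        targets=small_panel.targets[:1],
    )
    frac = (st.molecules["family_size"] >= 3).mean()
    assert abs(frac - surviving_family_fraction(cfg, 3)) < 0.03
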