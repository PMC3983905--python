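import numpy as np
import pytest

import chromaprof as cp
from chromaprof.synthetic import TurnoverParams, place_nucleosomes
from dataclasses import replace


class TestCohort:
    def test_determinism(self, small_config):
        a = cp.sample_gene_cohort(small_config)
        b = cp.sample_gene_cohort(small_config)
        assert a.genes == b.genes
        np.testing.assert_array_equal(a.activity, b.activity)
        np.testing.assert_array_equal(a.elongation, b.elongation)

    def test_empty_cohort(self):
        cfg = cp.default_sim_config(1, n_genes=0)
        assert cp.sample_gene_cohort(cfg).genes == []

    def test_genes_do_not_overlap(self, small_cohort):
        by_chrom = {}
        for g in small_cohort.genes:
            lo, hi = sorted((g.tss, g.tes))
            by_chrom.setdefault(g.chrom, []).append((lo, hi))
        for spans in by_chrom.values():
            spans.sort()
            for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
                assert h1 < l2

    def test_activity_quintiles_are_equal_sized(self):
        cfg = cp.default_sim_config(5, n_genes=2000, n_fragments=1000)
        co = cp.sample_gene_cohort(cfg)
        ranking = cp.rank_genes(dict(zip(co.gene_ids, co.activity)))
        groups = cp.quintile_split(ranking)
        assert [len(g) for g in groups.groups] == [400] * 5


class TestPlaceNucleosomes:
    def test_zero_fuzz_puts_plus1_dyad_at_entry_plus_73(self, small_cohort):
        arch = replace(cp.default_architecture(), fuzz_sd=0.0)
        nmap = place_nucleosomes(small_cohort, arch, "wt")
        assert nmap.plus_dyad(0, 1) == arch.plus1_entry + 73
        assert nmap.dyads[0][0] == arch.minus1_dyad

    def test_array_spacing_at_zero_fuzz(self, small_cohort):
        arch = replace(cp.default_architecture(), fuzz_sd=0.0)
        nmap = place_nucleosomes(small_cohort, arch, "wt")
        d = nmap.dyads[0][1:]
        assert np.allclose(np.diff(d), arch.repeat_length)

    def test_conditions_share_positions_but_scale_occupancy(self, small_cohort):
        wt = place_nucleosomes(small_cohort, condition="wt")
        mut = place_nucleosomes(small_cohort, condition="k510r")
        cond = cp.default_condition("k510r")
        for g in range(10):
            np.testing.assert_array_equal(wt.dyads[g], mut.dyads[g])
            ratio = mut.occupancy[g] / wt.occupancy[g]
            assert set(np.round(ratio, 6)) <= {cond.nuc_occ_promoter, cond.nuc_occ_body}

    def test_mean_realized_plus1_dyad_near_target(self):
        cfg = cp.default_sim_config(3, n_genes=1000, n_fragments=1000)
        co = cp.sample_gene_cohort(cfg)
        nmap = place_nucleosomes(co, condition="wt")
        arch = cp.default_architecture()
        realized = np.array([nmap.plus_dyad(g, 1) for g in range(1000)])
        assert abs(realized.mean() - arch.plus1_dyad) < 1.0
        assert realized.std() == pytest.approx(arch.fuzz_sd, rel=0.15)

    def test_no_dyads_inside_ndr(self, small_cohort):
        nmap = place_nucleosomes(small_cohort, condition="wt")
        arch = cp.default_architecture()
        # ideal positions avoid the NDR; realized jitter may graze its edges
        for g in range(20):
            inside = (nmap.dyads[g] > arch.ndr[0] + 3 * arch.fuzz_sd) & (
                nmap.dyads[g] < arch.ndr[1] - 3 * arch.fuzz_sd
            )
            assert not inside.any()


class TestSimulateLibrary:
    def test_determinism(self, small_cohort, small_config):
        a = cp.simulate_library("total_polii", "wt", small_cohort, config=small_config)
        b = cp.simulate_library("total_polii", "wt", small_cohort, config=small_config)
        np.testing.assert_array_equal(a.starts, b.starts)
        np.testing.assert_array_equal(a.ends, b.ends)

    def test_library_size_is_configured_count(self, small_cohort, small_config):
        lib = cp.simulate_library("nucleosome", "wt", small_cohort, config=small_config)
        assert lib.library_size == small_config.n_fragments

    def test_no_crosslinking_keeps_footprint_lengths(self, small_cohort, small_config):
        cfg = replace(small_config, p_x=0.0, background_fraction=0.0, n_fragments=5000)
        lib = cp.simulate_library("total_polii", "wt", small_cohort, config=cfg)
        spec = cp.load_presets()["footprints"]["total_polii"]
        assert lib.lengths.min() >= spec.min_len
        assert lib.lengths.max() <= spec.max_len

    def test_full_crosslinking_gives_mono_lengths(self, small_cohort, small_config):
        cfg = replace(small_config, p_x=1.0, background_fraction=0.0, n_fragments=5000)
        lib = cp.simulate_library("total_polii", "wt", small_cohort, config=cfg)
        assert lib.lengths.min() >= 111 and lib.lengths.max() <= 147

    def test_crosslink_fraction_matches_binomial(self, small_cohort):
        cfg = cp.default_sim_config(41, n_genes=400, n_fragments=100_000,
                                    p_x=0.3, background_fraction=0.0)
        co = cp.sample_gene_cohort(cfg)
        lib = cp.simulate_library("total_polii", "wt", co, config=cfg)
        # mono-sized fragments arise only from crosslinks (footprints <= 50 bp)
        n_mono = int((lib.lengths >= 111).sum())
        n = cfg.n_fragments
        sd = (n * 0.3 * 0.7) ** 0.5
        assert abs(n_mono - 0.3 * n) < 3 * sd

    def test_unknown_factor_errors(self, small_cohort, small_config):
        with pytest.raises(ValueError, match="unknown factor"):
            cp.simulate_library("h3k4me3", "wt", small_cohort, config=small_config)

    def test_wt_short_polii_peaks_at_tss(self, rpm_track_factory, small_cohort):
        track = rpm_track_factory("total_polii", "wt", size_class=cp.SHORT, mode="midpoint")
        profile = cp.mean_profile(
            cp.build_anchored_matrix(track, small_cohort.genes, "TSS", 500, 1000, 1)
        )
        peak = cp.estimate_peak_offset(profile, (-300, 500))
        assert abs(peak) <= 15

    def test_wt_chd1_declines_beyond_500(self, rpm_track_factory, small_cohort):
        track = rpm_track_factory("chd1_wt", "wt", size_class=cp.SHORT, mode="midpoint")
        profile = cp.mean_profile(
            cp.build_anchored_matrix(track, small_cohort.genes, "TSS", 500, 2000, 1)
        )
        v = profile.values
        offs = profile.offsets
        early = v[(offs >= 100) & (offs < 500)].mean()
        mid = v[(offs >= 600) & (offs < 1000)].mean()
        late = v[(offs >= 1200) & (offs < 1600)].mean()
        assert early > mid > late

    def test_k510r_mono_promoter_occupancy_below_wt(self, rpm_track_factory, small_cohort):
        wt = rpm_track_factory("nucleosome", "wt", size_class=cp.MONO, mode="span")
        mut = rpm_track_factory("nucleosome", "k510r", size_class=cp.MONO, mode="span")
        w = cp.WindowSpec("TSS", -350, 350)
        occ_wt = np.mean([cp.window_mean(wt, g, w) for g in small_cohort.genes])
        occ_mut = np.mean([cp.window_mean(mut, g, w) for g in small_cohort.genes])
        assert occ_mut < occ_wt


class TestSimulateCatchit:
    def test_flat_parameterization_is_flat(self, small_cohort, small_config):
        flat = TurnoverParams(basal=0.3, slope=0.0, body_basal=0.3, body_coupling=0.0,
                              delta=0.0, noise_sd=0.0, gene_noise_sd=0.0,
                              background_level=0.3)
        cond = replace(cp.default_condition("wt"), turnover=flat)
        track = cp.simulate_catchit(small_cohort, cond, small_config)
        for arr in track.data.values():
            np.testing.assert_allclose(arr, 0.3)

    def test_determinism(self, small_cohort, small_config):
        a = cp.simulate_catchit(small_cohort, "wt", small_config)
        b = cp.simulate_catchit(small_cohort, "wt", small_config)
        for c in a.data:
            np.testing.assert_array_equal(a.data[c], b.data[c])

    def test_k510r_promoter_signal_independent_of_activity(self, small_cohort, small_config):
        track = cp.simulate_catchit(small_cohort, "k510r", small_config)
        w = cp.WindowSpec("TSS", -150, 150)
        y = np.array([cp.window_mean(track, g, w) for g in small_cohort.genes])
        x = np.minimum(small_cohort.activity, cp.default_condition("wt").turnover.ceiling)
        slope = np.polyfit(x, y, 1)[0]
        # wild-type coupling for comparison
        track_wt = cp.simulate_catchit(small_cohort, "wt", small_config)
        y_wt = np.array([cp.window_mean(track_wt, g, w) for g in small_cohort.genes])
        slope_wt = np.polyfit(x, y_wt, 1)[0]
        assert abs(slope) < 0.1 * abs(slope_wt)

    def test_body_delta_shift(self, small_cohort, small_config):
        wt = cp.simulate_catchit(small_cohort, "wt", small_config)
        mut = cp.simulate_catchit(small_cohort, "k510r", small_config)
        delta = cp.default_condition("k510r").turnover.delta
        ras_wt = cp.catchit_region_mean(wt, small_cohort.genes, cp.BODY_TSS)
        ras_mut = cp.catchit_region_mean(mut, small_cohort.genes, cp.BODY_TSS)
        a = {r.gene_id: r.value for r in ras_wt}
        diffs = [r.value - a[r.gene_id] for r in ras_mut]
        assert np.mean(diffs) == pytest.approx(delta, abs=0.02)


class TestEstimators:
    def triangle_profile(self, peak, width=60, span=(-500, 1000)):
        offs = np.arange(*span)
        v = np.maximum(0.0, 1.0 - np.abs(offs - peak) / width)
        # add a -1 nucleosome bump and NDR so the minimum search is realistic
        v += np.maximum(0.0, 1.0 - np.abs(offs + 170) / width)
        return cp.Profile(offs, v, 1)

    @pytest.mark.parametrize("peak,entry", [(123, 50), (140, 67)])
    def test_entry_from_noiseless_peak(self, peak, entry):
        assert cp.estimate_plus1_entry(self.triangle_profile(peak)) == pytest.approx(
            entry, abs=1
        )

    def test_peak_offset_delta_function(self):
        offs = np.arange(-200, 500)
        v = np.zeros(len(offs), dtype=float)
        v[np.where(offs == 60)[0][0]] = 1.0
        assert cp.estimate_peak_offset(cp.Profile(offs, v, 1), (-200, 500)) == 60

    def test_equal_peaks_report_leftmost(self):
        offs = np.arange(-100, 300)
        v = np.zeros(len(offs), dtype=float)
        v[np.where(offs == 40)[0][0]] = 1.0
        v[np.where(offs == 200)[0][0]] = 1.0
        assert cp.estimate_peak_offset(cp.Profile(offs, v, 1), (-100, 300)) == 40

    def test_flat_profile_errors(self):
        p = cp.Profile(np.arange(100), np.ones(100), 1)
        with pytest.raises(ValueError, match="flat"):
            cp.estimate_peak_offset(p, (10, 90))

    def test_entry_recovered_from_small_wt_cohort(self, rpm_track_factory, small_cohort):
        track = rpm_track_factory("nucleosome", "wt", size_class=cp.MONO, mode="span")
        profile = cp.mean_profile(
            cp.build_anchored_matrix(track, small_cohort.genes, "TSS", 500, 1000, 1)
        )
        entry = cp.estimate_plus1_entry(profile)
        assert entry == pytest.approx(cp.default_architecture().plus1_entry, abs=12)
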