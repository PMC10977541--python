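"""CN estimation, five-state classification, mosaic fractions, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcnvseq.binning import BinCounts
from rcnvseq.genome import GenomeModel, build_bin_grid
from rcnvseq.model import (ClassificationThresholds, CopyNumberModel, classify_cn,
                           estimate_cn, gc_correct, infer_sex, mosaic_fraction,
                           segment_profile)
from rcnvseq.simulate import SequencingConfig, TruthEvent, simulate_case


class TestClassification:
    @pytest.mark.parametrize("cn,state", [
        (3.0, "duplication"),
        (2.5, "mosaic_trisomy"),
        (2.0, "disomy"),
        (1.5, "mosaic_monosomy"),
        (1.0, "deletion"),
    ])
    def test_canonical_values(self, cn, state):
        assert classify_cn(cn) == state

    @pytest.mark.parametrize("cn,state", [
        (0.0, "deletion"),
        (1.2, "mosaic_monosomy"),   # boundaries closed toward disomy at 1.8/2.2
        (1.8, "disomy"),
        (2.2, "disomy"),
        (2.8, "mosaic_trisomy"),
        (100.0, "duplication"),
    ])
    def test_boundary_convention(self, cn, state):
        assert classify_cn(cn) == state

    @given(st.floats(0.0, 10.0, allow_nan=False))
    def test_partition_is_total(self, cn):
        assert classify_cn(cn) in ("deletion", "mosaic_monosomy", "disomy",
                                   "mosaic_trisomy", "duplication")

    def test_dense_grid_partition_no_gaps(self):
        grid = np.round(np.arange(0.0, 4.0001, 0.0001), 4)
        states = classify_cn(grid)
        assert not any(s is None for s in states)
        # the state sequence is monotone: del -> mos-mono -> disomy -> mos-tri -> dup
        order = {"deletion": 0, "mosaic_monosomy": 1, "disomy": 2,
                 "mosaic_trisomy": 3, "duplication": 4}
        ranks = np.array([order[s] for s in states])
        assert np.all(np.diff(ranks) >= 0)

    def test_negative_rejected_and_order_enforced(self):
        with pytest.raises(ValueError):
            classify_cn(-0.1)
        with pytest.raises(ValueError):
            ClassificationThresholds(del_max=2.0, disomy_lo=1.8)


class TestMosaicFraction:
    @pytest.mark.parametrize("cn,direction,f", [
        (2.5, "gain", 0.5), (3.0, "gain", 1.0), (2.0, "gain", 0.0),
        (1.5, "loss", 0.5), (1.0, "loss", 1.0), (3.4, "gain", 1.0),  # clipped
    ])
    def test_values(self, cn, direction, f):
        assert mosaic_fraction(cn, direction) == pytest.approx(f)

    def test_inconsistent_direction_rejected(self):
        with pytest.raises(ValueError):
            mosaic_fraction(1.5, "gain")
        with pytest.raises(ValueError):
            mosaic_fraction(2.5, "loss")
        with pytest.raises(ValueError):
            mosaic_fraction(2.5, "sideways")


def _uniform_counts(grid, value=100.0):
    return BinCounts("s", grid, np.full(grid.n_bins, value))


class TestGcCorrection:
    def test_uniform_gc_is_identity(self):
        grid = build_bin_grid(GenomeModel({"chr1": 2_000_000}), 20_000)
        bc = BinCounts("s", grid, np.arange(100, dtype=float))
        out = gc_correct(bc)
        assert np.array_equal(out.counts, bc.counts)

    def test_zero_count_bin_stays_zero(self, toy_grid):
        counts = np.full(toy_grid.n_bins, 50.0)
        counts[7] = 0.0
        out = gc_correct(BinCounts("s", toy_grid, counts))
        assert out.counts[7] == 0.0

    def test_quadratic_bias_removed(self, toy_grid):
        seq = SequencingConfig(n_mapped=3_000_000, gc_bias=(1.5, -8.0), seed=11)
        bc = simulate_case(toy_grid, [], seq)
        out = gc_correct(bc)
        gc = toy_grid.gc
        strata = (gc // 0.05).astype(int)
        meds = []
        for s in np.unique(strata):
            sel = (strata == s) & toy_grid.autosomal
            if sel.sum() > 50:
                meds.append(np.median(out.counts[sel]))
        meds = np.array(meds)
        # per-GC-stratum medians equalised within 5%
        assert meds.max() / meds.min() < 1.05


class TestEstimateCn:
    def test_definitional_scaling(self, toy_grid):
        counts = np.full(toy_grid.n_bins, 80.0)
        counts[toy_grid.chrom_slice("chr1")] = 120.0  # 1.5x the baseline
        profile = estimate_cn(BinCounts("s", toy_grid, counts), "median")
        assert profile.chromosome_mean("chr2") == pytest.approx(2.0)
        assert profile.chromosome_mean("chr1") == pytest.approx(3.0)

    def test_scale_equivariance(self, toy_grid):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30, toy_grid.n_bins).astype(float)
        p1 = estimate_cn(BinCounts("s", toy_grid, counts))
        p2 = estimate_cn(BinCounts("s", toy_grid, counts * 7.5))
        assert np.allclose(p1.cn, p2.cn)

    def test_zero_sample_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            estimate_cn(BinCounts("s", toy_grid, np.zeros(toy_grid.n_bins)))

    def test_trisomy_recovery_toy(self, toy_grid):
        ev = TruthEvent.whole_chromosome(toy_grid.genome, "chr21", 3)
        for seed in range(3):
            bc = simulate_case(toy_grid, [ev], SequencingConfig(n_mapped=3_000_000,
                                                                seed=seed))
            res = CopyNumberModel(bc).fit()
            assert res.chromosome_cn.loc["chr21", "mean_cn"] == pytest.approx(3.0, abs=0.1)


class TestSexInference:
    @pytest.mark.parametrize("sex", ["XX", "XY"])
    def test_inferred_from_chry_dosage(self, toy_grid, sex):
        bc = simulate_case(toy_grid, [], SequencingConfig(n_mapped=1_000_000, seed=2),
                           sex=sex)
        res = CopyNumberModel(bc).fit()
        assert res.sex == sex
        # dosage-adjusted sex chromosomes classify as disomy
        assert res.chromosome_cn.loc["chrX", "state"] == "disomy"
        assert res.chromosome_cn.loc["chrY", "state"] == "disomy"


class TestSegmentation:
    def test_event_free_profile_one_disomy_segment_per_chromosome(self, toy_grid):
        profile = estimate_cn(_uniform_counts(toy_grid), "median")
        segs = segment_profile(profile, sex="XX")
        autosomal = [s for s in segs if s.chrom not in ("chrX", "chrY")]
        assert len(autosomal) == 22
        assert all(s.state == "disomy" for s in autosomal)
        assert all(s.n_bins == toy_grid.n_chrom_bins(s.chrom) for s in autosomal)

    def test_five_bin_duplication_called(self, toy_grid):
        counts = np.full(toy_grid.n_bins, 100.0)
        sl = toy_grid.chrom_slice("chr2")
        counts[sl.start + 10: sl.start + 15] = 150.0
        profile = estimate_cn(BinCounts("s", toy_grid, counts), "median")
        segs = [s for s in segment_profile(profile, sex="XX")
                if s.state != "disomy" and s.chrom not in ("chrX", "chrY")]
        assert len(segs) == 1
        assert segs[0].chrom == "chr2" and segs[0].state == "duplication"
        assert (segs[0].bin_start, segs[0].bin_stop) == (10, 15)

    def test_short_event_filtered_by_min_bins(self, toy_grid):
        counts = np.full(toy_grid.n_bins, 100.0)
        sl = toy_grid.chrom_slice("chr2")
        counts[sl.start + 10: sl.start + 13] = 150.0  # 3 bins = 60 kb
        profile = estimate_cn(BinCounts("s", toy_grid, counts), "median")
        segs = [s for s in segment_profile(profile, min_bins=5, sex="XX")
                if s.state != "disomy" and s.chrom not in ("chrX", "chrY")]
        assert segs == []

    def test_deletion_called(self, toy_grid):
        counts = np.full(toy_grid.n_bins, 100.0)
        sl = toy_grid.chrom_slice("chr3")
        counts[sl.start + 5: sl.start + 12] = 50.0
        profile = estimate_cn(BinCounts("s", toy_grid, counts), "median")
        segs = [s for s in segment_profile(profile, sex="XX")
                if s.state != "disomy" and s.chrom not in ("chrX", "chrY")]
        assert [s.state for s in segs] == ["deletion"]

    def test_whole_chromosome_event_not_in_segmental_calls(self, toy_grid):
        ev = TruthEvent.whole_chromosome(toy_grid.genome, "chr21", 3)
        bc = simulate_case(toy_grid, [ev], SequencingConfig(n_mapped=3_000_000, seed=4))
        res = CopyNumberModel(bc).fit()
        assert "chr21" in res.whole_chromosome_events.index
        assert all(s.chrom != "chr21" for s in res.event_segments)


def test_summary_contains_track_and_calls(toy_grid):
    bc = simulate_case(toy_grid, [TruthEvent.whole_chromosome(toy_grid.genome,
                                                              "chr18", 3)],
                       SequencingConfig(n_mapped=3_000_000, seed=6))
    res = CopyNumberModel(bc).fit()
    text = res.summary()
    assert "chr18" in text and "duplication" in text
    assert "inferred sex" in text


def test_noise_floor_confident_segments_bounded(hg19_grid):
    """On an event-free full-depth genome, boundary-noise segments are plentiful
    at the sensitivity tier but the confident tier stays within a few tens."""
    from dataclasses import replace

    seq = SequencingConfig(n_mapped=3_000_000)
    for seed in (0, 1):
        bc = simulate_case(hg19_grid, [], replace(seq, seed=seed))
        res = CopyNumberModel(bc, gc_correction=False).fit()
        segs = res.event_segments
        confident = [s for s in segs if s.confident]
        assert len(confident) < 60
        # none of the noise segments reaches the clinical 1-Mb floor
        assert all(s.size < 1_000_000 for s in segs)
        # and the chromosome-level track stays clean
        assert res.whole_chromosome_events.empty


def test_cn_plot_renders_24_panels(toy_grid, tmp_path):
    bc = simulate_case(toy_grid, [], SequencingConfig(n_mapped=200_000, seed=8))
    res = CopyNumberModel(bc).fit()
    out = tmp_path / "plot.png"
    fig = res.plot(path=out)
    assert out.exists() and out.stat().st_size > 0
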