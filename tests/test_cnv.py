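"""Segment base fractions, control-median logR, and CNV boundary calling."""

import numpy as np
import pytest

from catchseq import (
    DepthTrack,
    GenomicInterval,
    SimConfig,
    TargetRegion,
    call_cnv_segments,
    logr_track,
    segment_base_fractions,
    simulate_background_repeats,
    simulate_depth_track,
    simulate_repeat_annotation,
    tile_target,
)
from catchseq.cnv import DEFAULT_LOGR_FLOOR, _bridge_nans

from conftest import brute_segment_sums


def iv(s, e, chrom="chrT"):
    return GenomicInterval(chrom, s, e)


class TestTiling:
    def test_trailing_bin_rule(self):
        # 250 bp -> bins of 100, 100, 50 (trailer >= half bin kept, partial)
        bins, partial = tile_target(TargetRegion("t", [iv(0, 250)]), 100)
        assert [(b.start, b.end) for b in bins] == [(0, 100), (100, 200), (200, 250)]
        assert list(partial) == [False, False, True]

    def test_short_trailer_merged_into_previous(self):
        bins, partial = tile_target(TargetRegion("t", [iv(0, 240)]), 100)
        assert [(b.start, b.end) for b in bins] == [(0, 100), (100, 240)]
        assert list(partial) == [False, True]

    def test_bins_tile_target_exactly(self):
        target = TargetRegion("t", [iv(0, 1034), iv(2000, 2750)])
        bins, _ = tile_target(target, 100)
        assert sum(b.length for b in bins) == target.composite_size


class TestSegmentFractions:
    def test_uniform_depth_gives_equal_fractions(self):
        target = TargetRegion("t", [iv(0, 1000)])
        table = segment_base_fractions(DepthTrack("chrT", 0, np.full(1000, 7.0)), target)
        assert np.allclose(table.base_fraction, 0.1)
        assert table.base_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_coverage_errors(self):
        target = TargetRegion("t", [iv(0, 1000)])
        with pytest.raises(ValueError, match="no coverage"):
            segment_base_fractions(DepthTrack("chrT", 0, np.zeros(1000)), target)

    def test_matches_per_base_oracle(self, rng):
        target = TargetRegion("t", [iv(0, 1034)])
        depth = rng.integers(0, 40, 1034).astype(float)
        table = segment_base_fractions(DepthTrack("chrT", 0, depth), target)
        bounds = [(b.start, b.end) for b in table.bins]
        sums = brute_segment_sums(depth, bounds)
        total = sum(sums)
        for got, s in zip(table.base_fraction, sums):
            assert got == s / total


class TestLogrTrack:
    def mk(self, fracs):
        n = len(fracs)
        bins = [iv(i * 100, (i + 1) * 100) for i in range(n)]
        from catchseq.cnv import SegmentTable

        return SegmentTable("t", bins, np.asarray(fracs, float),
                            np.zeros(n, bool))

    def test_identity_gives_zero(self):
        case = self.mk([0.25, 0.25, 0.25, 0.25])
        assert np.allclose(logr_track(case, [case, case]), 0.0)

    def test_half_fraction_gives_minus_one(self):
        ctrl = self.mk([0.25, 0.25, 0.25, 0.25])
        case = self.mk([0.125, 0.25, 0.25, 0.375])
        assert logr_track(case, [ctrl])[0] == pytest.approx(-1.0)

    def test_zero_control_median_is_na_not_inf(self):
        ctrl = self.mk([0.0, 0.5, 0.5, 0.0])
        case = self.mk([0.1, 0.4, 0.4, 0.1])
        logr = logr_track(case, [ctrl])
        assert np.isnan(logr[0]) and np.isnan(logr[3])
        assert np.isfinite(logr[1:3]).all()

    def test_zero_case_fraction_clipped_to_floor(self):
        ctrl = self.mk([0.25, 0.25, 0.25, 0.25])
        case = self.mk([0.0, 0.4, 0.3, 0.3])
        assert logr_track(case, [ctrl])[0] == DEFAULT_LOGR_FLOOR

    def test_binning_mismatch_errors(self):
        with pytest.raises(ValueError, match="binning"):
            logr_track(self.mk([0.5, 0.5]), [self.mk([0.25] * 4)])

    def test_needs_controls(self):
        with pytest.raises(ValueError):
            logr_track(self.mk([1.0]), [])


class TestCallCnvSegments:
    def bins(self, n):
        return [iv(i * 100, (i + 1) * 100) for i in range(n)]

    def test_flat_track_no_calls(self, rng):
        logr = rng.normal(0, 0.05, 200)
        assert call_cnv_segments(logr, self.bins(200)) == []

    def test_clean_het_deletion_recovered_exactly(self):
        logr = np.zeros(100)
        logr[40:60] = -1.0
        calls = call_cnv_segments(logr, self.bins(100))
        assert len(calls) == 1
        c = calls[0]
        assert c.state == "het_del"
        assert (c.interval.start, c.interval.end) == (4000, 6000)
        assert c.mean_logR == pytest.approx(-1.0)
        assert c.n_bins == 20

    def test_duplication_called(self):
        logr = np.zeros(100)
        logr[10:30] = np.log2(1.5)
        calls = call_cnv_segments(logr, self.bins(100))
        assert [c.state for c in calls] == ["dup"]

    def test_short_runs_below_min_run_ignored(self):
        logr = np.zeros(100)
        logr[50:54] = -1.0  # 4 bins < min_run 5
        assert call_cnv_segments(logr, self.bins(100)) == []

    def test_all_na_track_warns_no_calls(self, caplog):
        logr = np.full(50, np.nan)
        assert call_cnv_segments(logr, self.bins(50)) == []

    def test_na_bridging_inside_event(self):
        logr = np.zeros(100)
        logr[40:60] = -1.0
        logr[48:51] = np.nan  # short NA run inside the deletion
        calls = call_cnv_segments(logr, self.bins(100))
        assert len(calls) == 1 and calls[0].n_bins == 20

    def test_long_na_run_breaks_calls(self):
        logr = np.zeros(100)
        logr[40:60] = -1.0
        logr[45:55] = np.nan  # longer than smooth_window
        calls = call_cnv_segments(logr, self.bins(100))
        assert all(c.n_bins < 20 for c in calls)

    def test_bridge_nans_helper(self):
        v = np.array([0.0, np.nan, np.nan, 3.0])
        out = _bridge_nans(v, 2)
        assert np.allclose(out, [0, 1, 2, 3])
        # leading NaN cannot be bridged
        v2 = np.array([np.nan, 1.0])
        assert np.isnan(_bridge_nans(v2, 2)[0])


class TestSimulationRecovery:
    """Generator-law recovery at reduced scale: a 100 kb target at ~100x."""

    BASE = dict(
        genome_size=800_000,
        target_start=300_000,
        target_size=100_000,
        repeat_fraction=0.3,
        enrichment=80.0,
    )

    def fractions(self, seed, n_reads, events=()):
        cfg = SimConfig(seed=seed, n_reads=n_reads,
                        cnv_events=list(events), **self.BASE)
        reps = simulate_repeat_annotation(SimConfig(seed=5, **self.BASE))
        bg = simulate_background_repeats(SimConfig(seed=5, **self.BASE))
        track, _ = simulate_depth_track(cfg, reps, bg)
        return segment_base_fractions(track, cfg.target)

    def test_control_vs_controls_median_logr_near_zero(self):
        tables = [self.fractions(seed, 120_000) for seed in range(4)]
        logr = logr_track(tables[0], tables)
        assert abs(np.nanmedian(logr)) < 0.05

    def test_het_deletion_and_duplication_levels(self):
        controls = [self.fractions(seed, 120_000) for seed in range(1, 5)]
        ev_del = (320_000, 340_000, 1)
        ev_dup = (360_000, 380_000, 3)
        case = self.fractions(99, 120_000, events=[ev_del, ev_dup])
        logr = logr_track(case, controls)
        bins = case.bins
        in_del = [i for i, b in enumerate(bins)
                  if b.start >= ev_del[0] and b.end <= ev_del[1]]
        in_dup = [i for i, b in enumerate(bins)
                  if b.start >= ev_dup[0] and b.end <= ev_dup[1]]
        assert np.nanmean(logr[in_del]) == pytest.approx(-1.0, abs=0.1)
        assert np.nanmean(logr[in_dup]) == pytest.approx(np.log2(1.5), abs=0.1)

    def test_calls_invariant_to_depth_scaling(self):
        controls = [self.fractions(seed, 120_000) for seed in range(1, 5)]
        ev = (320_000, 340_000, 1)
        cfg = SimConfig(seed=99, n_reads=120_000, cnv_events=[ev], **self.BASE)
        reps = simulate_repeat_annotation(SimConfig(seed=5, **self.BASE))
        bg = simulate_background_repeats(SimConfig(seed=5, **self.BASE))
        track, _ = simulate_depth_track(cfg, reps, bg)
        t1 = segment_base_fractions(track, cfg.target)
        t2 = segment_base_fractions(track.scaled(10.0), cfg.target)
        assert np.array_equal(t1.base_fraction, t2.base_fraction)
        l1 = logr_track(t1, controls)
        l2 = logr_track(t2, controls)
        assert np.array_equal(l1, l2, equal_nan=True)
        assert call_cnv_segments(l1, t1.bins) == call_cnv_segments(l2, t2.bins)
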