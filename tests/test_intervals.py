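"""Interval arithmetic, repeat classification, GC windows and masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catchseq import (
    GenomicInterval,
    MaskSpec,
    RepeatAnnotation,
    TargetRegion,
    build_mask,
    classify_repeats,
    gc_extreme_intervals,
    gc_windows,
    merge_intervals,
    subtract_intervals,
)
from catchseq.intervals import round1

from conftest import base_set, random_intervals


def iv(s, e, chrom="chrT"):
    return GenomicInterval(chrom, s, e)


class TestGenomicInterval:
    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_length_and_overlap(self):
        a, b = iv(10, 20), iv(19, 30)
        assert a.length == 10
        assert a.overlaps(b) and a.overlap_len(b) == 1
        assert not a.overlaps(iv(20, 30))
        assert not a.overlaps(GenomicInterval("chrX", 10, 20))


class TestMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(10, 20), (15, 30)], [(10, 30)]),
            ([], []),
            ([(10, 20), (20, 30)], [(10, 30)]),  # bookended coalesce
            ([(5, 8), (1, 3)], [(1, 3), (5, 8)]),
        ],
    )
    def test_examples(self, raw, expected):
        got = merge_intervals([iv(*t) for t in raw])
        assert [(g.start, g.end) for g in got] == expected

    def test_malformed_reports_index(self):
        with pytest.raises(ValueError, match="index 1"):
            merge_intervals([iv(0, 5), ("chrT", 9, 3)])

    def test_matches_per_base_oracle_on_random_sets(self, rng):
        ivs = random_intervals(rng, 1000)
        merged = merge_intervals(ivs)
        assert base_set(merged) == base_set(ivs)
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start or a.chrom != b.chrom

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)),
            max_size=30,
        )
    )
    def test_idempotent_and_order_invariant(self, raw):
        ivs = [iv(s, s + l) for s, l in raw]
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once
        assert merge_intervals(list(reversed(ivs))) == once

    def test_subtract_matches_set_difference(self, rng):
        keep = random_intervals(rng, 200)
        rem = random_intervals(rng, 200)
        got = subtract_intervals(keep, rem)
        assert base_set(got) == base_set(keep) - base_set(rem)


class TestClassifyRepeats:
    def target(self, size=209_200):
        return TargetRegion("t", [iv(0, size, "chr11")])

    def test_table_style_percentage(self):
        # one class spanning 58.8 kb of a 209.2 kb target -> 28.1%
        reps = []
        pos = 0
        for _ in range(147):  # 147 x 400 bp = 58.8 kb, element in [250,500]
            reps.append(
                RepeatAnnotation(iv(pos, pos + 400, "chr11"), 750, 400)
            )
            pos += 800
        table = classify_repeats(reps, self.target())
        assert table.loc[("size", "250-500 bp"), "percent"] == 28.1
        assert table.loc[("size", "250-500 bp"), "span_kb"] == 58.8

    def test_empty_annotation(self):
        table = classify_repeats([], self.target())
        assert (table.drop(index=("all", "non_repeat"))["span_kb"] == 0).all()
        assert table.loc[("all", "non_repeat"), "percent"] == 100.0

    @pytest.mark.parametrize(
        "element_length, expected_class",
        [(249, "<250 bp"), (250, "250-500 bp"), (500, "250-500 bp"), (501, ">500 bp")],
    )
    def test_size_boundary_rule(self, element_length, expected_class):
        rep = RepeatAnnotation(iv(0, 100, "chr11"), 700, element_length)
        assert rep.size_class == expected_class

    @pytest.mark.parametrize(
        "sw, expected_class",
        [(599, "<600 SW"), (600, "600-900 SW"), (900, "600-900 SW"), (901, ">900 SW")],
    )
    def test_sw_boundary_rule(self, sw, expected_class):
        rep = RepeatAnnotation(iv(0, 100, "chr11"), sw)
        assert rep.sw_class == expected_class

    def test_clipping_to_target(self):
        # element extends 300 bp past the target end; only 200 bp counted
        t = TargetRegion("t", [iv(0, 1000, "chr11")])
        rep = RepeatAnnotation(iv(800, 1300, "chr11"), 700, 500)
        table = classify_repeats([rep], t)
        assert table.loc[("all", "total"), "span_bp"] == 200
        # classified by element length (500 -> mid class), not clipped length
        assert table.loc[("size", "250-500 bp"), "span_bp"] == 200

    def test_overlap_resolved_by_higher_sw(self):
        t = TargetRegion("t", [iv(0, 1000, "chr11")])
        lo = RepeatAnnotation(iv(100, 400, "chr11"), 500, 300)
        hi = RepeatAnnotation(iv(300, 700, "chr11"), 950, 400)
        table = classify_repeats([lo, hi], t)
        # overlap bases (300-400) go to the higher-scoring element
        assert table.loc[("sw", "<600 SW"), "span_bp"] == 200
        assert table.loc[("sw", ">900 SW"), "span_bp"] == 400
        assert table.loc[("all", "total"), "span_bp"] == 600

    def test_schemes_partition_merged_span(self, rng):
        t = self.target(50_000)
        reps = [
            RepeatAnnotation(r, int(rng.integers(200, 1500)),
                             int(rng.integers(60, 1500)))
            for r in random_intervals(rng, 60, "chr11", 50_000, 800)
        ]
        table = classify_repeats(reps, t)
        total = table.loc[("all", "total"), "span_bp"]
        assert table.xs("size")["span_bp"].sum() == total
        assert table.xs("sw")["span_bp"].sum() == total
        assert total + table.loc[("all", "non_repeat"), "span_bp"] == t.composite_size


class TestGcWindows:
    def test_all_g_window_is_extreme(self):
        t = TargetRegion("t", [iv(0, 400)])
        w = gc_windows("G" * 400, t)
        assert w.loc[0, "gc_percent"] == 100.0 and bool(w.loc[0, "extreme"])

    def test_alternating_sequence_not_extreme(self):
        t = TargetRegion("t", [iv(0, 400)])
        w = gc_windows("GCAT" * 100, t)
        assert w.loc[0, "gc_percent"] == 50.0 and not w.loc[0, "extreme"]

    def test_exact_35_percent_boundary_not_extreme(self):
        seq = "G" * 140 + "A" * 260
        w = gc_windows(seq, TargetRegion("t", [iv(0, 400)]))
        assert w.loc[0, "gc_percent"] == 35.0 and not w.loc[0, "extreme"]

    def test_n_in_denominator_and_all_n_indeterminate(self):
        # 100 G + 300 N -> 25% GC but computed over full window
        seq = "G" * 100 + "N" * 300 + "N" * 400
        t = TargetRegion("t", [iv(0, 800)])
        w = gc_windows(seq, t)
        assert w.loc[0, "gc_percent"] == 25.0 and bool(w.loc[0, "extreme"])
        assert bool(w.loc[1, "indeterminate"]) and not w.loc[1, "extreme"]
        assert gc_extreme_intervals(w) == [iv(0, 400)]

    def test_trailing_partial_window_never_extreme(self):
        seq = "GCAT" * 100 + "G" * 100
        w = gc_windows(seq, TargetRegion("t", [iv(0, 500)]))
        assert bool(w.loc[1, "partial"])
        assert w.loc[1, "gc_percent"] == 100.0 and not w.loc[1, "extreme"]

    def test_windows_anchor_at_each_interval_start(self):
        t = TargetRegion("t", [iv(100, 500), iv(1000, 1400)])
        seq = "A" * 1400
        w = gc_windows(seq, t)
        assert list(w["start"]) == [100, 1000]


class TestBuildMask:
    def test_no_criteria_identity(self):
        t = TargetRegion("t", [iv(0, 1000)])
        masked, unmasked = build_mask(t, [], MaskSpec())
        assert masked.composite_size == 0
        assert unmasked.intervals == t.intervals

    def test_fully_repeat_target_errors(self):
        t = TargetRegion("t", [iv(0, 500)])
        reps = [RepeatAnnotation(iv(0, 500), 700, 500)]
        with pytest.raises(ValueError, match="empty unmasked"):
            build_mask(t, reps, MaskSpec(mask_all_repeats=True))

    def test_exclusive_criteria_enforced(self):
        with pytest.raises(ValueError):
            MaskSpec(mask_all_repeats=True, sw_range=(600, 900))

    def test_partition_is_exact(self, rng):
        t = TargetRegion("t", [iv(0, 10_000)])
        reps = [
            RepeatAnnotation(r, 700, int(rng.integers(100, 600)))
            for r in random_intervals(rng, 30)
        ]
        masked, unmasked = build_mask(t, reps, MaskSpec(mask_all_repeats=True))
        assert masked.composite_size + unmasked.composite_size == t.composite_size

    def test_size_range_mask_matches_per_base_oracle(self, rng):
        t = TargetRegion("t", [iv(0, 10_000)])
        reps = [
            RepeatAnnotation(r, 700, int(rng.integers(100, 900)))
            for r in random_intervals(rng, 40)
        ]
        spec = MaskSpec(repeat_size_range=(250, 500))
        masked, unmasked = build_mask(t, reps, spec)
        selected = [r.interval for r in reps if 250 <= r.element_length <= 500]
        expect_masked = base_set(t.intervals) & base_set(selected)
        assert base_set(masked.intervals) == expect_masked
        assert base_set(unmasked.intervals) == base_set(t.intervals) - expect_masked


@pytest.mark.parametrize(
    "x, expected",
    [(13.94, 13.9), (13.95, 14.0), (-2.25, -2.3), (0.0, 0.0), (8.849, 8.8)],
)
def test_round_half_away_from_zero(x, expected):
    assert round1(x) == expected
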