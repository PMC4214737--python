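"""Shared fixtures and independent brute-force oracles.

The oracles recompute interval set operations, coverage curves and segment
fractions base by base with plain Python sets/loops, independent of the
interval-arithmetic code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from catchseq import GenomicInterval, TargetRegion


# ---------------------------------------------------------------------------
# Brute-force per-base oracles
# ---------------------------------------------------------------------------


def base_set(intervals) -> set[tuple[str, int]]:
    """Every (chrom, position) covered by the intervals."""
    out = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            out.add((iv.chrom, p))
    return out


def intervals_from_base_set(bases: set[tuple[str, int]]) -> list[GenomicInterval]:
    """Minimal sorted disjoint intervals covering exactly ``bases``."""
    out = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, p in bases:
        by_chrom.setdefault(chrom, []).append(p)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomicInterval(chrom, start, prev + 1))
                start = p
            prev = p
        out.append(GenomicInterval(chrom, start, prev + 1))
    return out


def brute_coverage_percent(depth_values: np.ndarray, d: int) -> float:
    """Percent of bases with depth >= d, counted one base at a time."""
    n_cov = sum(1 for v in depth_values for _ in [0] if v >= d)
    return 100.0 * n_cov / len(depth_values)


def brute_segment_sums(depth_values, bin_bounds) -> list[float]:
    """Per-bin base sums by explicit python loops over [lo, hi) offsets."""
    sums = []
    for lo, hi in bin_bounds:
        total = 0
        for i in range(lo, hi):
            total += depth_values[i]
        sums.append(float(total))
    return sums


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chrT",
    span: int = 10_000,
    max_len: int = 400,
) -> list[GenomicInterval]:
    starts = rng.integers(0, span - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + l, span)))
        for s, l in zip(starts, lens)
        if min(s + l, span) > s
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_target():
    return TargetRegion("toy", [GenomicInterval("chrT", 0, 10_000)])
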