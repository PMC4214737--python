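"""Read filtering, on/off-target accounting, masked coverage curves and
repeat-stratified read yields for capture QC."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    SIZE_CLASSES,
    SW_CLASSES,
    GenomicInterval,
    MaskSpec,
    RepeatAnnotation,
    TargetRegion,
    build_mask,
    round1,
)

logger = logging.getLogger(__name__)

NON_REPEAT = "non_repeat"


@dataclass(frozen=True)
class ReadRecord:
    """Aligned read interval with mapping quality and duplicate flag."""

    interval: GenomicInterval
    mapq: int = 60
    is_duplicate: bool = False
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass
class DepthTrack:
    """Per-base depth over one contiguous chromosome span.

    ``depth[i]`` is the depth at genomic position ``start + i``.
    """

    chrom: str
    start: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if (self.depth < 0).any():
            raise ValueError("depths must be >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        """Depth values over ``iv``; requires the track to cover it."""
        if iv.chrom != self.chrom or iv.start < self.start or iv.end > self.end:
            raise ValueError(f"track does not cover {iv}")
        return self.depth[iv.start - self.start : iv.end - self.start]

    def scaled(self, factor: float) -> "DepthTrack":
        return DepthTrack(self.chrom, self.start, self.depth * factor)

    def padded(self, start: int, end: int) -> "DepthTrack":
        """Track extended with zero depth to cover at least [start, end)."""
        new_start = min(start, self.start)
        new_end = max(end, self.end)
        depth = np.zeros(new_end - new_start)
        depth[self.start - new_start : self.end - new_start] = self.depth
        return DepthTrack(self.chrom, new_start, depth)


def depth_from_reads(
    reads: Sequence[ReadRecord], chrom: str, start: int, end: int
) -> DepthTrack:
    """Per-base depth of read intervals over ``chrom:[start,end)``."""
    n = end - start
    diff = np.zeros(n + 1, dtype=np.int64)
    for r in reads:
        iv = r.interval
        if iv.chrom != chrom:
            continue
        s = max(iv.start, start) - start
        e = min(iv.end, end) - start
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    return DepthTrack(chrom, start, np.cumsum(diff[:-1]).astype(np.float64))


# ---------------------------------------------------------------------------
# Filtering and on/off classification
# ---------------------------------------------------------------------------


def filter_reads(
    reads: Sequence[ReadRecord],
    min_mapq: int = 20,
    drop_duplicates: bool = True,
) -> tuple[list[ReadRecord], dict]:
    """Keep reads with MAPQ >= ``min_mapq`` that are not flagged duplicates.

    Returns (kept reads, QC tally).  Duplication rate = duplicates / total,
    NA on empty input.
    """
    kept = []
    n_dup = n_lowq = 0
    for r in reads:
        if drop_duplicates and r.is_duplicate:
            n_dup += 1
            continue
        if r.mapq < min_mapq:
            n_lowq += 1
            continue
        kept.append(r)
    total = len(reads)
    tally = {
        "total": total,
        "kept": len(kept),
        "duplicates": n_dup,
        "low_mapq": n_lowq,
        "duplication_rate": (n_dup / total) if total else float("nan"),
    }
    return kept, tally


def mark_positional_duplicates(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Flag all but the first read at each identical (chrom, start, end).

    Positional criterion for inputs whose aligner did not set duplicate
    flags.  Input order decides which copy is kept.
    """
    seen: set[tuple[str, int, int]] = set()
    out = []
    for r in reads:
        key = (r.interval.chrom, r.interval.start, r.interval.end)
        if key in seen:
            out.append(
                ReadRecord(r.interval, r.mapq, True, r.mate_id)
            )
        else:
            seen.add(key)
            out.append(r)
    return out


def classify_on_off(
    reads: Sequence[ReadRecord],
    target: TargetRegion,
    rule: str = "overlap",
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split filtered reads into on-target and off-target sets.

    ``rule='overlap'``: on-target iff the read shares >= 1 bp with the target
    (default).  ``rule='midpoint'``: on-target iff the read midpoint falls in
    the target.  |on| + |off| = |input| always.
    """
    if rule not in ("overlap", "midpoint"):
        raise ValueError(f"unknown rule {rule!r}")
    known = target.chroms
    on, off = [], []
    warned = False
    for r in reads:
        if r.interval.chrom not in known:
            if not warned:
                logger.warning(
                    "reads on chroms outside the target (e.g. %s) counted "
                    "off-target",
                    r.interval.chrom,
                )
                warned = True
            off.append(r)
            continue
        if rule == "overlap":
            hit = any(r.interval.overlaps(iv) for iv in target.intervals)
        else:
            hit = target.contains_point(r.interval.chrom, r.interval.midpoint)
        (on if hit else off).append(r)
    return on, off


# ---------------------------------------------------------------------------
# Coverage-at-depth curves
# ---------------------------------------------------------------------------


def coverage_at_depth_curve(
    depth: DepthTrack,
    target: TargetRegion,
    depths: Sequence[int],
    mask: Optional[MaskSpec] = None,
    repeats: Sequence[RepeatAnnotation] = (),
    gc_flags: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Percent of (unmasked) targeted bases covered at >= d for each d.

    Masked bases leave both numerator and denominator.  The curve is
    monotone non-increasing in d and is 100% at d = 0.
    """
    if mask is not None:
        _, region = build_mask(target, repeats, mask, gc_flags)
    else:
        region = target
    vals = np.concatenate([depth.slice(iv) for iv in region.intervals])
    if vals.size == 0:
        raise ValueError("empty unmasked target")
    rows = [
        {
            "depth": int(d),
            "percent_covered": 100.0 * float((vals >= d).sum()) / vals.size,
        }
        for d in depths
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratified yields
# ---------------------------------------------------------------------------


class _RepeatLookup:
    """Per-base repeat-class lookup over the span each chrom's repeats cover.

    Where annotations overlap, the higher SW score wins — the same rule the
    span accounting uses.  Class ids index SIZE_CLASSES / SW_CLASSES; -1
    means non-repeat.
    """

    def __init__(self, repeats: Sequence[RepeatAnnotation]):
        self._by_chrom: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[RepeatAnnotation]] = {}
        for rep in repeats:
            per_chrom.setdefault(rep.interval.chrom, []).append(rep)
        for chrom, reps in per_chrom.items():
            lo = min(r.interval.start for r in reps)
            hi = max(r.interval.end for r in reps)
            size_id = np.full(hi - lo, -1, dtype=np.int8)
            sw_id = np.full(hi - lo, -1, dtype=np.int8)
            sw_val = np.full(hi - lo, -1, dtype=np.int64)
            for rep in reps:
                sc = SIZE_CLASSES.index(rep.size_class)
                wc = SW_CLASSES.index(rep.sw_class)
                seg = slice(rep.interval.start - lo, rep.interval.end - lo)
                win = sw_val[seg] < rep.sw_score
                size_id[seg] = np.where(win, sc, size_id[seg])
                sw_id[seg] = np.where(win, wc, sw_id[seg])
                sw_val[seg] = np.where(win, rep.sw_score, sw_val[seg])
            self._by_chrom[chrom] = (lo, size_id, sw_id)

    def class_ids(
        self, chrom: str, positions: np.ndarray, scheme: str
    ) -> np.ndarray:
        """Class id per position (-1 = non-repeat)."""
        out = np.full(len(positions), -1, dtype=np.int8)
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return out
        lo, size_id, sw_id = entry
        arr = size_id if scheme == "size" else sw_id
        idx = positions - lo
        inside = (idx >= 0) & (idx < len(arr))
        out[inside] = arr[idx[inside]]
        return out


def stratified_yield(
    reads: Sequence[ReadRecord],
    target: TargetRegion,
    repeats: Sequence[RepeatAnnotation],
    scheme: str = "size",
    on_off_rule: str = "overlap",
) -> pd.DataFrame:
    """On/off-target read yields stratified by repeat class.

    Each (already filtered) read is assigned exactly one stratum — the repeat
    class at its midpoint, or non-repeat — and counted on- or off-target.
    Percentages are of the total yield, so the table sums to 100% up to
    rounding.  ``repeats`` may include annotations outside the target so that
    off-target reads stratify by the genome-wide repeat structure.
    """
    if scheme not in ("size", "sw"):
        raise ValueError(f"unknown scheme {scheme!r}")
    classes = list(SIZE_CLASSES if scheme == "size" else SW_CLASSES)
    strata = [NON_REPEAT] + classes
    on, off = classify_on_off(reads, target, rule=on_off_rule)
    lookup = _RepeatLookup(repeats)
    counts = {s: {"on": 0, "off": 0} for s in strata}
    for rset, key in ((on, "on"), (off, "off")):
        by_chrom: dict[str, list[int]] = {}
        for r in rset:
            by_chrom.setdefault(r.interval.chrom, []).append(r.interval.midpoint)
        for chrom, mids in by_chrom.items():
            ids = lookup.class_ids(chrom, np.asarray(mids, dtype=np.int64), scheme)
            counts[NON_REPEAT][key] += int((ids == -1).sum())
            for i, label in enumerate(classes):
                counts[label][key] += int((ids == i).sum())
    total = len(reads)
    rows = []
    for s in strata:
        c_on, c_off = counts[s]["on"], counts[s]["off"]
        rows.append(
            {
                "stratum": s,
                "on_count": c_on,
                "off_count": c_off,
                "on_percent": round1(100 * c_on / total) if total else 0.0,
                "off_percent": round1(100 * c_off / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
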