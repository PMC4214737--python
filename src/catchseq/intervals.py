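"""Genomic interval arithmetic, repeat classification, GC windowing, masking.

All coordinates are 0-based half-open (BED convention) internally; 1-based
dialects (UCSC rmsk, Bismark coverage) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Repeat size-class labels and half-open predicates on the annotated element
#: length.  "250 bp to 500 bp" is read inclusively on both ends, so the size
#: bins are [1,250), [250,500], (500, inf); Smith-Waterman bins analogous with
#: [600, 900].
SIZE_CLASSES = ("<250 bp", "250-500 bp", ">500 bp")
SW_CLASSES = ("<600 SW", "600-900 SW", ">900 SW")


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (matches printed tables)."""
    if x != x:  # NaN
        return x
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RepeatAnnotation:
    """Repeat element with its RepeatMasker-style score and full length.

    ``element_length`` is the annotated length of the whole element, which may
    exceed the in-target overlap (the element can extend past the target);
    classification into size bins uses the element length, span accounting
    uses the target-clipped overlap.
    """

    interval: GenomicInterval
    sw_score: int
    element_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sw_score < 0:
            raise ValueError(f"sw_score must be >= 0, got {self.sw_score}")
        if self.element_length is None:
            object.__setattr__(self, "element_length", self.interval.length)
        elif self.element_length < 1:
            raise ValueError("element_length must be >= 1")

    @property
    def size_class(self) -> str:
        n = self.element_length
        if n < 250:
            return SIZE_CLASSES[0]
        if n <= 500:
            return SIZE_CLASSES[1]
        return SIZE_CLASSES[2]

    @property
    def sw_class(self) -> str:
        s = self.sw_score
        if s < 600:
            return SW_CLASSES[0]
        if s <= 900:
            return SW_CLASSES[1]
        return SW_CLASSES[2]


@dataclass
class TargetRegion:
    """Named captured target: a set of disjoint, sorted intervals."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def composite_size(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def offsets(self) -> list[tuple[GenomicInterval, int]]:
        """Each interval with its offset into the composite coordinate."""
        out, off = [], 0
        for iv in self.intervals:
            out.append((iv, off))
            off += iv.length
        return out

    def contains_point(self, chrom: str, pos: int) -> bool:
        return any(
            iv.chrom == chrom and iv.start <= pos < iv.end for iv in self.intervals
        )


@dataclass
class MaskSpec:
    """Which target bases to exclude from coverage accounting.

    At most one repeat criterion (size range, SW range, or all-repeats) may be
    active; the GC-extreme flag can be combined with any of them.  Ranges are
    inclusive on both ends; ``None`` bounds are open.
    """

    repeat_size_range: Optional[tuple[Optional[int], Optional[int]]] = None
    sw_range: Optional[tuple[Optional[int], Optional[int]]] = None
    mask_all_repeats: bool = False
    gc_extremes: bool = False

    def __post_init__(self) -> None:
        active = sum(
            [
                self.repeat_size_range is not None,
                self.sw_range is not None,
                self.mask_all_repeats,
            ]
        )
        if active > 1:
            raise ValueError("at most one repeat mask criterion may be active")
        for rng in (self.repeat_size_range, self.sw_range):
            if rng is not None and rng[0] is not None and rng[1] is not None:
                if rng[0] > rng[1]:
                    raise ValueError(f"empty range {rng}")

    def repeat_selected(self, rep: RepeatAnnotation) -> bool:
        if self.mask_all_repeats:
            return True
        if self.repeat_size_range is not None:
            lo, hi = self.repeat_size_range
            n = rep.element_length
            return (lo is None or n >= lo) and (hi is None or n <= hi)
        if self.sw_range is not None:
            lo, hi = self.sw_range
            s = rep.sw_score
            return (lo is None or s >= lo) and (hi is None or s <= hi)
        return False


# ---------------------------------------------------------------------------
# Interval set arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, total covered bases preserved.

    Adjacent (bookended) intervals are coalesced.  Raises ``ValueError`` with
    the offending index for malformed input.
    """
    ivs = list(intervals)
    for i, iv in enumerate(ivs):
        if not isinstance(iv, GenomicInterval):
            try:
                ivs[i] = GenomicInterval(*iv)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed interval at index {i}: {exc}") from exc
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def subtract_intervals(
    keep: Iterable[GenomicInterval], remove: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference ``keep \\ remove``, both merged first."""
    keep_m = merge_intervals(keep)
    rem_m = merge_intervals(remove)
    out: list[GenomicInterval] = []
    for iv in keep_m:
        cur = iv.start
        for r in rem_m:
            if r.chrom != iv.chrom or r.end <= cur or r.start >= iv.end:
                continue
            if r.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, r.start))
            cur = max(cur, r.end)
            if cur >= iv.end:
                break
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set intersection of two interval sets (merged output)."""
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    out = []
    for iv in a_m:
        for r in b_m:
            if r.chrom != iv.chrom:
                continue
            s, e = max(iv.start, r.start), min(iv.end, r.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return merge_intervals(out)


def clip_to_target(
    intervals: Iterable[GenomicInterval], target: TargetRegion
) -> list[GenomicInterval]:
    return intersect_intervals(intervals, target.intervals)


# ---------------------------------------------------------------------------
# Repeat classification
# ---------------------------------------------------------------------------


def _class_arrays(
    repeats: Sequence[RepeatAnnotation], target: TargetRegion
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base (composite coordinate) class index and SW score arrays.

    Class index encodes the size class (0..2); -1 = non-repeat.  Where
    elements of different classes overlap, the higher SW score wins (logged).
    A parallel array holds the SW class index for the same winning element.
    """
    n = target.composite_size
    size_id = np.full(n, -1, dtype=np.int8)
    sw_id = np.full(n, -1, dtype=np.int8)
    sw_val = np.full(n, -1, dtype=np.int64)
    conflicts = 0
    for rep in repeats:
        sc = SIZE_CLASSES.index(rep.size_class)
        wc = SW_CLASSES.index(rep.sw_class)
        for iv, off in target.offsets():
            s = max(rep.interval.start, iv.start)
            e = min(rep.interval.end, iv.end)
            if rep.interval.chrom != iv.chrom or s >= e:
                continue
            a, b = off + s - iv.start, off + e - iv.start
            seg = slice(a, b)
            occupied = sw_val[seg] >= 0
            differing = occupied & (
                (size_id[seg] != sc) | (sw_id[seg] != wc)
            )
            if differing.any():
                conflicts += int(differing.sum())
            win = sw_val[seg] < rep.sw_score
            size_id[seg] = np.where(win, sc, size_id[seg])
            sw_id[seg] = np.where(win, wc, sw_id[seg])
            sw_val[seg] = np.where(win, rep.sw_score, sw_val[seg])
    if conflicts:
        logger.warning(
            "overlapping repeats of different classes on %d bases; "
            "resolved by higher SW score",
            conflicts,
        )
    return size_id, sw_id


def classify_repeats(
    repeats: Sequence[RepeatAnnotation], target: TargetRegion
) -> pd.DataFrame:
    """Per-class clipped repeat span within the target.

    Returns a table with one row per class plus ``total`` and ``non_repeat``
    rows: scheme ('size', 'sw', 'all'), clipped span in kb (1 decimal) and
    percent of the composite target size (1 decimal, half away from zero) —
    the "on target (%)" accounting of capture-target repeat structure.
    """
    size_id, sw_id = _class_arrays(repeats, target)
    total_bp = target.composite_size
    rows = []

    def add(scheme: str, label: str, bp: int) -> None:
        rows.append(
            {
                "scheme": scheme,
                "class": label,
                "span_bp": int(bp),
                "span_kb": round1(bp / 1000),
                "percent": round1(100 * bp / total_bp),
            }
        )

    repeat_bp = int((size_id >= 0).sum())
    add("all", "total", repeat_bp)
    for i, label in enumerate(SIZE_CLASSES):
        add("size", label, int((size_id == i).sum()))
    for i, label in enumerate(SW_CLASSES):
        add("sw", label, int((sw_id == i).sum()))
    add("all", "non_repeat", total_bp - repeat_bp)
    return pd.DataFrame(rows).set_index(["scheme", "class"])


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------


def gc_windows(
    sequence,
    target: TargetRegion,
    window: int = 400,
    low: float = 0.35,
    high: float = 0.65,
) -> pd.DataFrame:
    """Non-overlapping GC windows anchored at each target interval's start.

    ``sequence`` maps chrom name to a full-chromosome string (a dict or a
    pyfaidx.Fasta); a bare string is accepted for single-chrom targets.
    Ambiguity codes count in the denominator; an all-N window is flagged
    indeterminate and never enters the extreme mask.  A trailing partial
    window (< ``window`` bp) is computed over its actual length but is never
    flagged extreme (insufficient support).

    Extremes are strict: GC < ``low`` or GC > ``high`` (a window at exactly
    35.0% is not extreme).
    """
    rows = []
    for iv in target.intervals:
        if isinstance(sequence, str):
            chrom_seq = sequence
        else:
            chrom_seq = str(sequence[iv.chrom])
        if len(chrom_seq) < iv.end:
            raise ValueError(
                f"sequence for {iv.chrom} (len {len(chrom_seq)}) does not "
                f"cover target end {iv.end}"
            )
        for ws in range(iv.start, iv.end, window):
            we = min(ws + window, iv.end)
            seq = chrom_seq[ws:we].upper()
            n = len(seq)
            gc = seq.count("G") + seq.count("C")
            valid = n - seq.count("N")
            partial = n < window
            indeterminate = valid == 0
            frac = gc / n
            extreme = (
                not partial
                and not indeterminate
                and (frac < low or frac > high)
            )
            rows.append(
                {
                    "chrom": iv.chrom,
                    "start": ws,
                    "end": we,
                    "gc_percent": round1(100 * frac),
                    "gc_fraction": frac,
                    "extreme": extreme,
                    "indeterminate": indeterminate,
                    "partial": partial,
                }
            )
    return pd.DataFrame(rows)


def gc_extreme_intervals(gc_table: pd.DataFrame) -> list[GenomicInterval]:
    """Merged intervals of the GC-extreme windows (the GC mask)."""
    flagged = gc_table[gc_table["extreme"]]
    return merge_intervals(
        GenomicInterval(r.chrom, r.start, r.end) for r in flagged.itertuples()
    )


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------


def build_mask(
    target: TargetRegion,
    repeats: Sequence[RepeatAnnotation] = (),
    spec: Optional[MaskSpec] = None,
    gc_flags: Optional[pd.DataFrame] = None,
) -> tuple[TargetRegion, TargetRegion]:
    """Split the target into (masked, unmasked) regions per a MaskSpec.

    Masked bases are meant to leave both numerator and denominator of any
    downstream coverage rate; masked + unmasked partition the target exactly.
    Raises ``ValueError`` if nothing would remain unmasked.
    """
    spec = spec or MaskSpec()
    mask_ivs: list[GenomicInterval] = []
    if spec.mask_all_repeats or spec.repeat_size_range or spec.sw_range:
        mask_ivs.extend(
            rep.interval for rep in repeats if spec.repeat_selected(rep)
        )
    if spec.gc_extremes:
        if gc_flags is None:
            raise ValueError("gc_extremes mask requested but no gc_flags given")
        mask_ivs.extend(gc_extreme_intervals(gc_flags))
    masked_ivs = intersect_intervals(mask_ivs, target.intervals)
    unmasked_ivs = subtract_intervals(target.intervals, masked_ivs)
    if not unmasked_ivs:
        raise ValueError(f"empty unmasked target for {target.name}")
    masked = TargetRegion(f"{target.name}|masked", masked_ivs)
    unmasked = TargetRegion(f"{target.name}|unmasked", unmasked_ivs)
    assert masked.composite_size + unmasked.composite_size == target.composite_size
    return masked, unmasked
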