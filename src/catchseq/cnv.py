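"""Read-depth logR copy-number analysis over a captured target.

The target is tiled with non-overlapping 100 bp segments; for each sample
the fraction of its total on-target aligned bases per segment is computed.
A case sample's per-bin logR is log2 of its base fraction over the median
base fraction of control samples — this cancels the capture and sequencer
depth biases shared by all samples, so a heterozygous deletion sits near
logR = -1 and a 3-copy duplication near log2(1.5).  CNV boundaries are
called from thresholded runs of smoothed logR at bin resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .intervals import GenomicInterval, TargetRegion

logger = logging.getLogger(__name__)

DEFAULT_LOGR_FLOOR = -8.0

#: Smoothed-logR thresholds per copy-number state.  Midway heuristics around
#: the expected levels: het deletion -1, hom deletion at the clip floor,
#: single-copy duplication log2(1.5) ~ +0.585.
DEFAULT_THRESHOLDS = {"het_del": -0.4, "hom_del": -2.5, "dup": 0.32}


@dataclass
class SegmentTable:
    """100-bp bins tiling a target with one sample's base fractions.

    ``base_fraction[i]`` is the fraction of the sample's total on-target
    aligned bases falling in bin i; fractions sum to 1.  A trailing bin
    shorter than half the bin size is merged into its predecessor, otherwise
    kept and flagged partial.
    """

    target_name: str
    bins: list[GenomicInterval]
    base_fraction: np.ndarray
    partial: np.ndarray
    bin_size: int = 100
    total_bases: float = 0.0

    def same_binning(self, other: "SegmentTable") -> bool:
        return self.bins == other.bins


@dataclass(frozen=True)
class CnvCall:
    """One called copy-number segment at bin-edge resolution."""

    interval: GenomicInterval
    state: str  # het_del | hom_del | dup
    mean_logR: float
    n_bins: int


def tile_target(target: TargetRegion, bin_size: int = 100) -> tuple[
    list[GenomicInterval], np.ndarray
]:
    """Consecutive bins per target interval with the trailing-bin rule:
    a trailer of >= bin_size/2 is kept (flagged partial), a shorter one is
    merged into the previous bin."""
    bins: list[GenomicInterval] = []
    partial: list[bool] = []
    for iv in target.intervals:
        pos = iv.start
        while pos < iv.end:
            end = min(pos + bin_size, iv.end)
            rem = iv.end - end
            if 0 < rem < (bin_size + 1) // 2:
                # absorb the short trailer now
                end = iv.end
            bins.append(GenomicInterval(iv.chrom, pos, end))
            partial.append(end - pos != bin_size)
            pos = end
    return bins, np.asarray(partial, dtype=bool)


def segment_base_fractions(
    depth: DepthTrack, target: TargetRegion, bin_size: int = 100
) -> SegmentTable:
    """Per-bin aligned-base sums normalized by the sample total.

    Raises ``ValueError`` when the sample has no coverage on the target.
    """
    bins, partial = tile_target(target, bin_size)
    sums = np.empty(len(bins), dtype=np.float64)
    for i, b in enumerate(bins):
        sums[i] = depth.slice(b).sum()
    total = sums.sum()
    if total == 0:
        raise ValueError("no coverage on target")
    return SegmentTable(
        target_name=target.name,
        bins=bins,
        base_fraction=sums / total,
        partial=partial,
        bin_size=bin_size,
        total_bases=float(total),
    )


def logr_track(
    case: SegmentTable,
    controls: Sequence[SegmentTable],
    floor: float = DEFAULT_LOGR_FLOOR,
) -> np.ndarray:
    """Per-bin logR = log2(case fraction / median control fraction).

    Bins where the control median is 0 are NA (NaN), never +/-inf; bins where
    the case fraction is 0 are clipped to ``floor``.
    """
    if not controls:
        raise ValueError("need at least one control sample")
    for c in controls:
        if not case.same_binning(c):
            raise ValueError("control binning does not match case binning")
    ctrl = np.vstack([c.base_fraction for c in controls])
    med = np.median(ctrl, axis=0)
    logr = np.full(len(case.bins), np.nan)
    ok = med > 0
    case_f = case.base_fraction
    pos = ok & (case_f > 0)
    logr[pos] = np.log2(case_f[pos] / med[pos])
    logr[ok & (case_f == 0)] = floor
    np.clip(logr, floor, None, out=logr)
    return logr


def _bridge_nans(values: np.ndarray, max_run: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs no longer than ``max_run``."""
    out = values.copy()
    isna = np.isnan(out)
    if not isna.any():
        return out
    idx = np.arange(len(out))
    i = 0
    while i < len(out):
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < len(out) and isna[j]:
            j += 1
        if 0 < i and j < len(out) and (j - i) <= max_run:
            out[i:j] = np.interp(idx[i:j], [i - 1, j], [out[i - 1], out[j]])
        i = j
    return out


def rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median, shrinking the window at the edges; NaN-aware
    (a window of all-NaN stays NaN)."""
    s = pd.Series(values)
    return (
        s.rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def call_cnv_segments(
    logr: np.ndarray,
    bins: Sequence[GenomicInterval],
    smooth_window: int = 5,
    thresholds: Optional[dict[str, float]] = None,
    min_run: int = 5,
    floor: float = DEFAULT_LOGR_FLOOR,
) -> list[CnvCall]:
    """Threshold-and-run CNV caller on a smoothed logR track.

    NA runs no longer than ``smooth_window`` are bridged by interpolation;
    longer NA runs stay NA and break call runs.  The smoothed track is
    classified per bin (dup / het_del / hom_del / normal) and maximal
    same-state runs of at least ``min_run`` bins become calls whose
    boundaries are the first/last bin edges of the run.  ``mean_logR`` is the
    mean of the raw (unsmoothed) logR over the run, NaN bins excluded.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    logr = np.asarray(logr, dtype=np.float64)
    if len(logr) != len(bins):
        raise ValueError("logr length does not match bins")
    if np.isnan(logr).all():
        logger.warning("all-NA logR track; no CNV calls")
        return []
    bridged = _bridge_nans(logr, smooth_window)
    smooth = rolling_median(bridged, smooth_window)

    state = np.full(len(smooth), "normal", dtype=object)
    with np.errstate(invalid="ignore"):
        state[smooth >= thresholds["dup"]] = "dup"
        state[smooth <= thresholds["het_del"]] = "het_del"
        state[smooth <= thresholds["hom_del"]] = "hom_del"
    state[np.isnan(smooth)] = "na"

    calls: list[CnvCall] = []
    i = 0
    n = len(state)
    while i < n:
        st = state[i]
        j = i
        while j < n and state[j] == st:
            j += 1
        if st not in ("normal", "na") and (j - i) >= min_run:
            chrom = bins[i].chrom
            if all(b.chrom == chrom for b in bins[i:j]):
                raw = logr[i:j]
                mean = float(np.nanmean(raw)) if not np.isnan(raw).all() else float("nan")
                calls.append(
                    CnvCall(
                        interval=GenomicInterval(chrom, bins[i].start, bins[j - 1].end),
                        state=st,
                        mean_logR=mean,
                        n_bins=j - i,
                    )
                )
            else:
                logger.warning("call run spans chromosomes; skipped")
        i = j
    return calls


def segment_table_frame(
    table: SegmentTable, logr: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Tidy per-bin frame (chrom, start, end, base_fraction[, logR])."""
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in table.bins],
            "start": [b.start for b in table.bins],
            "end": [b.end for b in table.bins],
            "base_fraction": table.base_fraction,
            "partial": table.partial,
        }
    )
    if logr is not None:
        df["logR"] = logr
    return df
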