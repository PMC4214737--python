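"""CpG depth filtering and region-level percent-methylation summaries.

Operates downstream of an external bisulfite aligner: input is per-CpG
methylated/unmethylated read counts (Bismark-coverage style).  Sites below a
minimum depth (default 20x) are removed before any percent-methylation value
is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, round1


@dataclass(frozen=True)
class CpGRecord:
    """One CpG site (C or CG dyad) with methylation call counts."""

    position: GenomicInterval
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError(
                f"negative counts at {self.position.chrom}:{self.position.start}"
            )
        if self.position.length not in (1, 2):
            raise ValueError("CpG position must span 1 (C) or 2 (dyad) bases")

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def percent(self) -> float:
        """Percent methylation (0-100, 1 decimal); NaN at zero depth."""
        if self.depth == 0:
            return float("nan")
        return round1(100 * self.meth_count / self.depth)


def merge_dyads(records: Sequence[CpGRecord]) -> list[CpGRecord]:
    """Sum strand-split C calls at adjacent positions into one dyad record.

    Two length-1 records at (chrom, p) and (chrom, p+1) are combined into a
    single length-2 dyad covering [p, p+2); applied before depth filtering so
    a dyad's depth pools both strands.
    """
    by_pos = {}
    for r in sorted(records, key=lambda r: (r.position.chrom, r.position.start)):
        key = (r.position.chrom, r.position.start)
        if r.position.length == 1:
            prev = by_pos.get((r.position.chrom, r.position.start - 1))
            if prev is not None and prev.position.length == 1:
                merged = CpGRecord(
                    GenomicInterval(
                        r.position.chrom, prev.position.start, r.position.end
                    ),
                    prev.meth_count + r.meth_count,
                    prev.unmeth_count + r.unmeth_count,
                )
                by_pos[(r.position.chrom, prev.position.start)] = merged
                continue
        by_pos[key] = r
    return list(by_pos.values())


def filter_cpgs(
    records: Sequence[CpGRecord], min_depth: int = 20
) -> list[CpGRecord]:
    """Keep CpGs with depth >= ``min_depth`` (sites under 20x are unreliable
    for percent methylation and are dropped by default)."""
    return [r for r in records if r.depth >= min_depth]


def region_summary(
    records: Sequence[CpGRecord],
    regions: Sequence[GenomicInterval],
    names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-region CpG count, mean percent and depth-weighted percent.

    Regions without surviving CpGs are reported with NaN, never dropped.  A
    CpG is assigned to a region when its start position lies inside it.
    """
    if names is None:
        names = [
            f"{r.chrom}:{r.start}-{r.end}" for r in regions
        ]
    rows = []
    for name, region in zip(names, regions):
        hits = [
            r
            for r in records
            if r.position.chrom == region.chrom
            and region.start <= r.position.start < region.end
        ]
        n = len(hits)
        if n == 0:
            rows.append(
                {
                    "region": name,
                    "n_cpgs": 0,
                    "mean_percent": float("nan"),
                    "weighted_percent": float("nan"),
                    "total_depth": 0,
                }
            )
            continue
        depths = [r.depth for r in hits]
        percents = [100 * r.meth_count / r.depth for r in hits]
        total_meth = sum(r.meth_count for r in hits)
        total_depth = sum(depths)
        rows.append(
            {
                "region": name,
                "n_cpgs": n,
                "mean_percent": round1(sum(percents) / n),
                "weighted_percent": round1(100 * total_meth / total_depth),
                "total_depth": total_depth,
            }
        )
    return pd.DataFrame(rows).set_index("region")
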