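"""Seeded synthetic capture-sequencing data generator.

Emulates the phenomena the analysis modules measure, on a single simulated
chromosome carrying one contiguous capture target embedded in off-target
background:

* a repeat annotation with a configurable class mix (element size and
  Smith-Waterman score bins) on and off target;
* capture reads whose start positions are drawn from per-base weights —
  on-target bases are enriched ``enrichment``-fold over background,
  repeat-origin capture is suppressed per class by a blocking efficiency
  (emulating Cot-1 DNA fold), unblocked repeat probes cross-hybridize
  off-target repeats, and copy-number-c intervals scale on-target weights by
  c/2;
* binomially sampled per-CpG methylation counts over a region-wise true
  methylation profile.

The total number of sequenced reads per run is fixed (as when a fixed number
of aligned reads is sampled per experiment), so stronger repeat blocking
both raises on-target and lowers off-target read counts.

Everything is driven by one ``numpy`` Generator seeded from ``SimConfig.seed``;
identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coverage import DepthTrack, ReadRecord
from .intervals import (
    SIZE_CLASSES,
    SW_CLASSES,
    GenomicInterval,
    RepeatAnnotation,
    TargetRegion,
)
from .methylation import CpGRecord

#: Element-length range (bp) drawn for each size class, and the SW score
#: assigned to it by default (small repeats diverged/low-scoring, large
#: repeats young/high-scoring).
CLASS_LENGTH_RANGES = {
    "<250 bp": (60, 249),
    "250-500 bp": (250, 500),
    ">500 bp": (501, 1500),
}
CLASS_SW_SCORES = {"<250 bp": 400, "250-500 bp": 750, ">500 bp": 950}
#: Element lengths used when spans are requested per SW class.
SW_CLASS_SW_SCORES = {"<600 SW": 400, "600-900 SW": 750, ">900 SW": 950}


@dataclass
class SimConfig:
    """Study conditions for one simulated capture run.

    Defaults mirror a typical contiguous ~250 kb capture target that is
    about half repeat, captured at high on-target enrichment with strong
    (but imperfect) per-class repeat blocking.
    """

    seed: int = 0
    chrom: str = "chr11"
    genome_size: int = 5_000_000
    target_start: int = 2_000_000
    target_size: int = 250_000
    repeat_fraction: float = 0.5
    class_mix: dict = field(
        default_factory=lambda: {
            "<250 bp": 0.25,
            "250-500 bp": 0.55,
            ">500 bp": 0.20,
        }
    )
    #: exact per-class spans (bp), keyed by size or SW class labels;
    #: overrides repeat_fraction/class_mix when set
    repeat_spans: Optional[dict] = None
    background_repeat_fraction: float = 0.5
    enrichment: float = 100.0
    blocking_efficiency: dict = field(
        default_factory=lambda: {c: 0.9 for c in SIZE_CLASSES}
    )
    n_reads: int = 200_000
    read_length: int = 100
    #: (genomic start, genomic end, copy number in {0,1,2,3})
    cnv_events: list = field(default_factory=list)
    low_mapq_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    #: (genomic start, genomic end, true methylation level in [0,1])
    meth_profile: Optional[list] = None
    n_cpgs: int = 200
    depth_per_cpg: float = 50.0

    @property
    def target_end(self) -> int:
        return self.target_start + self.target_size

    @property
    def target(self) -> TargetRegion:
        return TargetRegion(
            "sim_target",
            [GenomicInterval(self.chrom, self.target_start, self.target_end)],
        )

    def validate(self) -> None:
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        for b in self.blocking_efficiency.values():
            if not 0 <= b <= 1:
                raise ValueError("blocking efficiencies must be in [0, 1]")
        if self.target_end > self.genome_size:
            raise ValueError("target extends past simulated genome")
        for s, e, c in self.cnv_events:
            if not (self.target_start <= s < e <= self.target_end):
                raise ValueError(f"cnv event ({s},{e}) outside target")
            if c not in (0, 1, 2, 3):
                raise ValueError(f"unsupported copy number {c}")
        if self.meth_profile:
            for _, _, p in self.meth_profile:
                if not 0 <= p <= 1:
                    raise ValueError("methylation levels must be in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream ``stream`` for this config."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------


def _partition_span(span: int, lo: int, hi: int) -> list[int]:
    """Split ``span`` exactly into element lengths within [lo, hi]."""
    if span == 0:
        return []
    if span < lo:
        raise ValueError(f"span {span} smaller than minimum element {lo}")
    n, rem = divmod(span, hi)
    if rem == 0:
        return [hi] * n
    if rem >= lo:
        return [hi] * n + [rem]
    # borrow from one full chunk so the remainder is feasible
    a = lo
    b = hi + rem - lo
    if n < 1 or b < lo or b > hi:
        raise ValueError(f"cannot partition {span} into [{lo},{hi}] elements")
    return [hi] * (n - 1) + [a, b]


def _place_elements(
    lengths: Sequence[int],
    region_start: int,
    region_end: int,
    rng: np.random.Generator,
) -> list[int]:
    """Random non-overlapping starts for elements within a region."""
    total = sum(lengths)
    free = (region_end - region_start) - total
    if free < 0:
        raise ValueError("elements do not fit in region")
    offsets = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = []
    consumed = 0
    for off, length in zip(offsets, lengths):
        starts.append(region_start + int(off) + consumed)
        consumed += length
    return starts


def _spans_by_class(config: SimConfig) -> tuple[dict, str]:
    """(requested span per class, scheme) from config."""
    if config.repeat_spans is not None:
        keys = set(config.repeat_spans)
        if keys <= set(SIZE_CLASSES):
            return dict(config.repeat_spans), "size"
        if keys <= set(SW_CLASSES):
            return dict(config.repeat_spans), "sw"
        raise ValueError(f"unknown repeat class keys {keys}")
    total = config.repeat_fraction * config.target_size
    mix_sum = sum(config.class_mix.values())
    if mix_sum <= 0 and total > 0:
        raise ValueError("class_mix sums to zero with nonzero repeat_fraction")
    return (
        {k: int(round(total * v / mix_sum)) for k, v in config.class_mix.items()},
        "size",
    )


def simulate_repeat_annotation(
    config: SimConfig,
    region: Optional[tuple[int, int]] = None,
    repeat_fraction: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[RepeatAnnotation]:
    """Non-overlapping repeat elements with the requested class mix.

    By default generates the on-target annotation; ``region`` and
    ``repeat_fraction`` override the span and density (used internally for
    off-target background).  Realized per-class spans match the request
    exactly up to one element trimmed to stay within its class length range.
    """
    config.validate()
    if rng is None:
        rng = config.rng(stream=1)
    if region is None:
        region = (config.target_start, config.target_end)
    if repeat_fraction is not None:
        # density override (background flanks): class_mix at the given density
        total_req = repeat_fraction * (region[1] - region[0])
        mix_sum = sum(config.class_mix.values())
        if total_req == 0 or mix_sum == 0:
            return []
        spans = {
            k: int(round(total_req * v / mix_sum))
            for k, v in config.class_mix.items()
        }
        scheme = "size"
    else:
        spans, scheme = _spans_by_class(config)
    if sum(spans.values()) >= (region[1] - region[0]):
        raise ValueError("requested repeat spans fill or exceed the region")

    lengths: list[int] = []
    classes: list[str] = []
    for cls, span in spans.items():
        if scheme == "size":
            lo, hi = CLASS_LENGTH_RANGES[cls]
        else:
            lo, hi = CLASS_LENGTH_RANGES["250-500 bp"]
        for n in _partition_span(int(span), lo, hi):
            lengths.append(n)
            classes.append(cls)
    order = rng.permutation(len(lengths))
    lengths = [lengths[i] for i in order]
    classes = [classes[i] for i in order]
    starts = _place_elements(lengths, region[0], region[1], rng)
    out = []
    for start, length, cls in zip(starts, lengths, classes):
        sw = (
            CLASS_SW_SCORES[cls] if scheme == "size" else SW_CLASS_SW_SCORES[cls]
        )
        out.append(
            RepeatAnnotation(
                GenomicInterval(config.chrom, start, start + length),
                sw_score=sw,
                element_length=length,
            )
        )
    return out


def simulate_background_repeats(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[RepeatAnnotation]:
    """Off-target repeat annotation over both flanks of the target."""
    if rng is None:
        rng = config.rng(stream=2)
    out: list[RepeatAnnotation] = []
    for region in ((0, config.target_start), (config.target_end, config.genome_size)):
        if region[1] - region[0] < 2000:
            continue
        out.extend(
            simulate_repeat_annotation(
                config,
                region=region,
                repeat_fraction=config.background_repeat_fraction,
                rng=rng,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Capture reads
# ---------------------------------------------------------------------------


def _blocking_for(rep: RepeatAnnotation, config: SimConfig) -> float:
    eff = config.blocking_efficiency
    if rep.size_class in eff:
        return eff[rep.size_class]
    if rep.sw_class in eff:
        return eff[rep.sw_class]
    return 0.0


def capture_weights(
    config: SimConfig,
    target_repeats: Sequence[RepeatAnnotation],
    background_repeats: Sequence[RepeatAnnotation] = (),
) -> np.ndarray:
    """Per-base read-start sampling weight over the simulated chromosome.

    background non-repeat 1; background repeat 1 + e(1-b) (cross-
    hybridization of unblocked repeat probes); on-target non-repeat e;
    on-target repeat e(1-b); copy-number-c event scales on-target by c/2.
    """
    w = np.ones(config.genome_size, dtype=np.float64)
    e = config.enrichment
    for rep in background_repeats:
        b = _blocking_for(rep, config)
        w[rep.interval.start : rep.interval.end] = 1.0 + e * (1.0 - b)
    w[config.target_start : config.target_end] = e
    for rep in target_repeats:
        b = _blocking_for(rep, config)
        w[rep.interval.start : rep.interval.end] = e * (1.0 - b)
    for s, ev_end, c in config.cnv_events:
        w[s:ev_end] *= c / 2.0
    return w


def sample_read_starts(
    config: SimConfig,
    weights: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample ``n_reads`` read start positions from the weight track."""
    if rng is None:
        rng = config.rng(stream=3)
    w = weights.copy()
    w[config.genome_size - config.read_length + 1 :] = 0.0
    cdf = np.cumsum(w)
    if cdf[-1] <= 0:
        raise ValueError("all-zero sampling weights")
    u = rng.random(config.n_reads) * cdf[-1]
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def simulate_capture_reads(
    config: SimConfig,
    target_repeats: Optional[Sequence[RepeatAnnotation]] = None,
    background_repeats: Optional[Sequence[RepeatAnnotation]] = None,
) -> tuple[list[ReadRecord], dict]:
    """Simulated aligned capture reads plus generation metadata.

    Returns (reads, info); ``info`` holds the annotations, the weight track
    and the analytic expected on-target fraction under the >=1 bp overlap
    rule, for law-recovery checks.
    """
    config.validate()
    if target_repeats is None:
        target_repeats = simulate_repeat_annotation(config)
    if background_repeats is None:
        background_repeats = simulate_background_repeats(config)
    w = capture_weights(config, target_repeats, background_repeats)
    rng = config.rng(stream=3)
    starts = sample_read_starts(config, w, rng)
    n = len(starts)
    mapqs = np.full(n, 60, dtype=np.int64)
    if config.low_mapq_fraction > 0:
        mapqs[rng.random(n) < config.low_mapq_fraction] = 10
    dups = np.zeros(n, dtype=bool)
    if config.duplicate_fraction > 0:
        dups = rng.random(n) < config.duplicate_fraction
    reads = [
        ReadRecord(
            GenomicInterval(config.chrom, int(s), int(s) + config.read_length),
            mapq=int(q),
            is_duplicate=bool(d),
        )
        for s, q, d in zip(starts, mapqs, dups)
    ]
    info = {
        "target_repeats": list(target_repeats),
        "background_repeats": list(background_repeats),
        "weights": w,
        "expected_on_target_fraction": expected_on_target_fraction(config, w),
        "seed": config.seed,
    }
    return reads, info


def expected_on_target_fraction(config: SimConfig, weights: np.ndarray) -> float:
    """Closed-form expected fraction of reads overlapping the target by
    >= 1 bp: the weight mass of start positions in
    (target_start - read_length, target_end)."""
    w = weights.copy()
    w[config.genome_size - config.read_length + 1 :] = 0.0
    lo = max(0, config.target_start - config.read_length + 1)
    return float(w[lo : config.target_end].sum() / w.sum())


def simulate_depth_track(
    config: SimConfig,
    target_repeats: Optional[Sequence[RepeatAnnotation]] = None,
    background_repeats: Optional[Sequence[RepeatAnnotation]] = None,
) -> tuple[DepthTrack, dict]:
    """Per-base on-target depth from a simulated run, without materializing
    per-read records (read sampling is identical to simulate_capture_reads
    given the same config and annotations)."""
    config.validate()
    if target_repeats is None:
        target_repeats = simulate_repeat_annotation(config)
    if background_repeats is None:
        background_repeats = simulate_background_repeats(config)
    w = capture_weights(config, target_repeats, background_repeats)
    starts = sample_read_starts(config, w, config.rng(stream=3))
    ends = starts + config.read_length
    t0, t1 = config.target_start, config.target_end
    keep = (ends > t0) & (starts < t1)
    s = np.clip(starts[keep], t0, t1) - t0
    e = np.clip(ends[keep], t0, t1) - t0
    diff = np.zeros(t1 - t0 + 1, dtype=np.int64)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    depth = np.cumsum(diff[:-1]).astype(np.float64)
    info = {
        "target_repeats": list(target_repeats),
        "background_repeats": list(background_repeats),
        "n_on_target_reads": int(keep.sum()),
        "expected_on_target_fraction": expected_on_target_fraction(config, w),
    }
    return DepthTrack(config.chrom, t0, depth), info


def reads_for_mean_depth(config: SimConfig, mean_depth: float) -> int:
    """Total reads needed for an expected on-target mean depth, given the
    config's enrichment/blocking/repeat structure (CNV events excluded so
    controls and cases get comparable totals)."""
    base = SimConfig(**{**config.__dict__, "cnv_events": [], "seed": config.seed})
    reps = simulate_repeat_annotation(base)
    bg = simulate_background_repeats(base)
    w = capture_weights(base, reps, bg)
    frac = expected_on_target_fraction(base, w)
    n = mean_depth * config.target_size / config.read_length / frac
    return int(np.ceil(n))


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def default_meth_profile(config: SimConfig) -> list[tuple[int, int, float]]:
    """Three equal regions at low / intermediate / high methylation."""
    third = config.target_size // 3
    t0 = config.target_start
    return [
        (t0, t0 + third, 0.10),
        (t0 + third, t0 + 2 * third, 0.50),
        (t0 + 2 * third, config.target_end, 0.90),
    ]


def simulate_methylation(config: SimConfig) -> list[CpGRecord]:
    """Per-CpG dyad counts: depth ~ Poisson(depth_per_cpg), methylated calls
    ~ Binomial(depth, regional true level)."""
    config.validate()
    rng = config.rng(stream=4)
    profile = config.meth_profile or default_meth_profile(config)
    positions = np.sort(
        rng.choice(
            np.arange(config.target_start, config.target_end - 2, 2),
            size=config.n_cpgs,
            replace=False,
        )
    )
    levels = np.empty(config.n_cpgs)
    levels.fill(np.nan)
    for s, e, p in profile:
        sel = (positions >= s) & (positions < e)
        levels[sel] = p
    if np.isnan(levels).any():
        raise ValueError("meth_profile does not cover all simulated CpGs")
    depths = rng.poisson(config.depth_per_cpg, size=config.n_cpgs)
    meth = rng.binomial(depths, levels)
    return [
        CpGRecord(
            GenomicInterval(config.chrom, int(p), int(p) + 2),
            meth_count=int(m),
            unmeth_count=int(d - m),
        )
        for p, d, m in zip(positions, depths, meth)
    ]
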