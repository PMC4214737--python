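"""Repeat-structure accounting of a capture target.

Generates a repeat annotation with fixed per-class spans inside a 209.2 kb
target and tabulates each class's clipped span and percent of the target —
the table one would build from a RepeatMasker track before deciding how
much Cot-1 blocking a capture needs.  Also flags 400 bp GC-extreme windows.
"""

from catchseq import (
    GenomicInterval,
    SimConfig,
    TargetRegion,
    classify_repeats,
    gc_extreme_intervals,
    gc_windows,
    simulate_repeat_annotation,
)

cfg = SimConfig(
    seed=101,
    genome_size=1_000_000,
    target_start=300_000,
    target_size=209_200,
    repeat_spans={"<250 bp": 29_100, "250-500 bp": 58_800, ">500 bp": 24_100},
)
repeats = simulate_repeat_annotation(cfg)
table = classify_repeats(repeats, cfg.target)
print(table)
print()
print("-> span_kb is the repeat span clipped to the target; percent is the "
      "share of the 209.2 kb target each class occupies.")

# a toy sequence whose first 46 windows are pure G (GC extreme)
seq = "G" * (46 * 400) + "GCAT" * ((209_200 - 46 * 400) // 4)
target = TargetRegion("chr11_target", [GenomicInterval("chr11", 0, 209_200)])
mask = gc_extreme_intervals(gc_windows(seq, target))
span = sum(iv.length for iv in mask)
print(f"GC-extreme windows (<35% or >65% GC): {span/1000:.1f} kb "
      f"({100*span/209_200:.1f}% of target)")
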