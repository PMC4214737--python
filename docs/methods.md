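# Methods

## Coordinates and conventions

All coordinates are 0-based half-open internally (BED native). 1-based
dialects are converted at the I/O edge only: UCSC rmsk dumps may be read
with `one_based_starts=True`, wiggle blocks are 1-based by definition, and
Bismark-coverage CpG positions are 1-based inclusive. Percentages in
printed tables are rounded to one decimal, half away from zero.

## Repeat classification

A repeat annotation carries its genomic interval, RepeatMasker-style
Smith–Waterman (SW) score, and the annotated element length. Two binning
schemes are used: element size — <250 bp, 250–500 bp (inclusive on both
ends), >500 bp — and SW score — <600, 600–900 (inclusive), >900. The class
of a repeat is decided by its **element length** (or SW score), while span
accounting uses the **target-clipped overlap**; an element extending past
the target is classified by its full length but contributes only its
in-target bases. Where elements of different classes overlap, the base goes
to the higher SW score (a warning reports how many bases were contested).
Classification is computed on a per-base class array over the composite
target, which makes the partition property (size classes and SW classes
each sum exactly to the merged repeat span) hold by construction; the
interval-arithmetic paths (merge, subtract, masking) are independent code
and are cross-checked against per-base brute force in the tests.

## GC windows and masks

GC content is computed in non-overlapping 400 bp windows anchored at each
target interval's start. A window is GC-extreme iff GC < 35% or GC > 65%
strictly (exactly 35.0% is not extreme). Ambiguity codes count in the
denominator; an all-N window is flagged indeterminate and never masks. A
trailing partial window is computed over its actual length but is never
flagged extreme — a sub-window gives insufficient support for masking.
A mask specification activates at most one repeat criterion (size range, SW
range, or all repeats), optionally combined with the GC-extreme windows;
masked bases leave both numerator and denominator of every coverage rate,
and masked + unmasked partition the target exactly (an empty unmasked
remainder is an error, never a silent zero division).

## Probe mass arithmetic

BAC template pooling splits the total input mass (typically 4 µg)
proportionally to each clone's covered span; overlapping clones each count
their own span and the proportional split renormalizes, so mass is
conserved exactly. The theoretical target yield of a library pool is
`library_mass × target_size / genome_size` in pg; the probe quantity per
hybridization is a fixed multiple of that yield (default 2500×). The
diploid genome size default is 6.2 × 10⁹ bp (2 × ~3.1 Gb male human
genome); the constant is configurable and echoed in every report rather
than hidden, since small differences in the assumed genome size shift the
yield proportionally.

## Read QC

Reads are kept iff MAPQ ≥ 20 (inclusive) and not flagged duplicate; a
positional duplicate marker (identical chrom/start/end) is provided for
inputs without aligner flags. On-target means ≥ 1 bp overlap with the
target (a midpoint rule is available behind a flag). Reads are counted
singly, not as pairs; the mate key is retained for future pair-level
accounting. Stratified yields assign each read exactly one stratum — the
repeat class at the read midpoint, or non-repeat — which is deterministic
and order-free for reads straddling repeat edges; annotations outside the
target let off-target reads stratify by genome-wide repeat structure.

## CNV logR

Each target interval is tiled with consecutive 100 bp bins; a trailing bin
of ≥ 50 bp is kept and flagged partial, a shorter one is merged into its
predecessor. Per-bin aligned-base sums are normalized by the sample's total
on-target bases, which removes sequencing-depth scale exactly: multiplying
a depth track by any positive constant leaves every fraction, logR value
and call bit-identical. logR is log2(case fraction / median control
fraction); bins with zero control median are NA (never ±inf), and zero case
fractions clip to a floor of −8 (configurable).

No boundary-calling algorithm is prescribed by the underlying protocol, so
the caller is the simplest method that meets the ±1-bin recovery property:
interior NA runs no longer than the smoothing window (default 5 bins) are
linearly interpolated, the track is smoothed with a centered rolling median
(window 5, which preserves step edges), per-bin states are assigned by
thresholds (het_del ≤ −0.4, hom_del ≤ −2.5, dup ≥ +0.32 — roughly midway
between the expected levels 0, −1, floor, and +0.58), and maximal
same-state runs of ≥ 5 bins become calls. Mean logR of a call is taken from
the unsmoothed track. Changepoint methods are deliberately out of scope.
A known caveat: when a CNV covers a large fraction of the target, the
base-fraction normalization slightly inflates out-of-CNV logR in that
sample; no renormalization is applied.

## Methylation

Strand-split C calls at adjacent positions are summed into one CpG dyad
before depth filtering (toggleable), so a dyad's depth pools both strands.
Sites below 20× depth are removed before any percent value is used; the
filter is monotone in the threshold. Region summaries report both the plain
mean of per-CpG percents and the depth-weighted percent (total methylated
calls / total calls); regions without surviving CpGs report NA and are
never dropped.

## Synthetic data generator

The generator emulates one contiguous capture target (default 250 kb,
half repeat) centered in a 5 Mb single-chromosome background. Reads are
fixed-length (100 bp) with start positions drawn from a per-base weight
track:

| base | weight |
|---|---|
| background non-repeat | 1 |
| background repeat, class *k* | 1 + e·(1 − b_k) |
| on-target non-repeat | e |
| on-target repeat, class *k* | e·(1 − b_k) |
| inside a copy-number-c event | on-target weight × c/2 |

with enrichment e (default 100) and per-class blocking efficiency b_k
(default 0.9, emulating strong Cot-1 blocking). The off-target repeat term
models unblocked repeat probes cross-hybridizing genome-wide repeats; with
the total sequenced read count held fixed per run (as when a fixed number
of aligned reads is sampled per condition), increasing b_k simultaneously
raises on-target and lowers off-target read counts — the qualitative
Cot-1 titration behavior the QC module must detect. The expected on-target
fraction has a closed form (the weight mass of start positions within a
read length of the target) and is returned with every simulation for
law-recovery tests.

Repeat annotations are non-overlapping elements whose lengths are drawn
per class (<250: 60–249 bp, 250–500, >500: 501–1500 bp; SW scores 400 /
750 / 950 by class) and placed uniformly; per-class spans can be requested
exactly, which the table-accounting checks use. Methylation counts are
binomial per CpG dyad (depth ~ Poisson, default 50×) over a region-wise
true-level profile (default thirds at 10/50/90%).

What the generator does **not** model: sequencing errors and base
qualities, GC-dependent amplification bias, realistic insert-size
distributions, paired-end structure, mappability. Passing tests therefore
demonstrate that the analyses recover the generative laws they assume
(enrichment, blocking direction, copy-number scaling, binomial counts),
not that they are robust to every artifact of real libraries.

All randomness flows from one seed through named `SeedSequence` streams
(annotation / background / reads / methylation), so identical configs are
bit-identical and sub-components can be regenerated independently.

## Problem sizes used in tests and the acceptance script

Table accounting runs at the two study target sizes (209.2 and 247.6 kb)
and is exact. CNV recovery uses a 250 kb target at ~200× with 6 controls
(~830 k reads per sample); generator-law unit tests use a 100 kb target at
~100×. The blocking-direction check uses four runs of 300 k reads at
blocking 0.3/0.5/0.7/0.9. Oracle-equivalence checks run 100 random
instances of ≤ 10 kb against per-base brute force. The full suite and the
acceptance script each complete in well under a minute on one core.

## Known limitations

* Boundary resolution is limited to the 100 bp bin grid; sub-bin
  breakpoints and inversions are out of scope.
* The CNV caller's fixed thresholds assume the control median is built from
  predominantly diploid samples; a CNV shared by most controls will shift
  the reference.
* Repeat "size" classification uses the annotated element length, not the
  in-target overlap length; both are defensible readings of size-binned
  repeat tables, and the choice is logged per run.
* On-target percentages count reads, not fragments; duplicate removal
  happens before on/off classification.
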