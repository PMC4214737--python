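"""Depth-filter simulated bisulfite CpG counts and summarize per region.

CpG dyads are simulated at three true methylation levels (10/50/90%) with
~50x depth, filtered at the 20x minimum, and summarized per region; the
depth-weighted percent recovers the simulated truth.
"""

from catchseq import (
    GenomicInterval,
    SimConfig,
    filter_cpgs,
    region_summary,
    simulate_methylation,
)
from catchseq.simulate import default_meth_profile

cfg = SimConfig(seed=42, n_cpgs=300, depth_per_cpg=50.0)
records = simulate_methylation(cfg)
kept = filter_cpgs(records, min_depth=20)
print(f"{len(kept)}/{len(records)} CpGs pass the 20x depth filter")

profile = default_meth_profile(cfg)
regions = [GenomicInterval(cfg.chrom, s, e) for s, e, _ in profile]
names = [f"true_{100*p:.0f}pct" for _, _, p in profile]
print(region_summary(kept, regions, names=names))
print("-> weighted_percent pools methylated calls over all reads in the "
      "region; it should sit near each region's simulated truth.")
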