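"""Mass arithmetic for BAC probe pooling and per-hybridization probe quantity.

Probe synthesis starts from pooled BAC clone DNA: each clone contributes
template mass in proportion to the share of the composite target it covers.
Per hybridization, the theoretical mass yield of target fragments in a
library is the library mass scaled by target:genome size, and the probe
quantity is a large fixed multiple (default 2500x) of that yield.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Approximate male human diploid genome size in bp.  The published protocol
#: names "male human diploid genome size" without a number; 6.2e9 (2 x ~3.1 Gb)
#: is used and always echoed in reports.
DEFAULT_GENOME_SIZE = 6.2e9

#: Probe : theoretical-target-yield mass ratio that typically puts 75-80% of
#: aligned reads on target.
DEFAULT_PROBE_RATIO = 2500.0

#: Cot-1 DNA : library mass fold used in the current capture protocol.
DEFAULT_COT1_FOLD = 40.0


@dataclass(frozen=True)
class BacClone:
    """A BAC clone and the composite-target span (bp) it covers."""

    name: str
    covered_span: int

    def __post_init__(self) -> None:
        if self.covered_span < 1:
            raise ValueError(f"clone {self.name}: covered_span must be >= 1")


def pool_bac_masses(
    clones: list[BacClone], total_mass: float
) -> dict[str, float]:
    """Per-clone template mass: (clone span / total span) x total mass.

    Overlapping clones each count their own span; the proportional split
    renormalizes so masses always sum to ``total_mass`` (conserved to
    floating tolerance).
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be > 0")
    if not clones:
        raise ValueError("need at least one clone")
    total_span = sum(c.covered_span for c in clones)
    if total_span <= 0:
        raise ValueError("zero total covered span")
    return {c.name: total_mass * c.covered_span / total_span for c in clones}


def theoretical_yield(
    target_size: float,
    library_mass: float,
    genome_size: float = DEFAULT_GENOME_SIZE,
) -> float:
    """Theoretical mass yield (same units as ``library_mass``) of target
    fragments within a library: library_mass x target_size / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if target_size < 0:
        raise ValueError("target_size must be >= 0")
    if target_size > genome_size:
        warnings.warn(
            "target_size exceeds genome_size; yield computed anyway",
            stacklevel=2,
        )
    return library_mass * target_size / genome_size


def probe_mass_required(
    yield_mass: float, ratio: float = DEFAULT_PROBE_RATIO
) -> float:
    """Probe mass for one hybridization: ratio x theoretical target yield."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return ratio * yield_mass


@dataclass
class HybridizationPlan:
    """Full mass plan for one hybridization reaction.

    Masses are in picograms; ``cot1_fold`` is the Cot-1 DNA : library mass
    ratio and is carried for the report only.
    """

    library_mass: float
    target_size: int
    genome_size: float = DEFAULT_GENOME_SIZE
    probe_ratio: float = DEFAULT_PROBE_RATIO
    cot1_fold: float = DEFAULT_COT1_FOLD
    theoretical_yield: float = field(init=False)
    probe_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.library_mass < 0:
            raise ValueError("library_mass must be >= 0")
        self.theoretical_yield = theoretical_yield(
            self.target_size, self.library_mass, self.genome_size
        )
        self.probe_mass = probe_mass_required(
            self.theoretical_yield, self.probe_ratio
        )

    def report(self) -> str:
        lines = [
            "hybridization plan",
            f"  library mass        : {self.library_mass:.6g} pg",
            f"  target size         : {self.target_size} bp",
            f"  genome size         : {self.genome_size:.6g} bp",
            f"  theoretical yield   : {self.theoretical_yield:.6g} pg",
            f"  probe:yield ratio   : {self.probe_ratio:.6g}",
            f"  probe mass          : {self.probe_mass:.6g} pg",
            f"  Cot-1 fold          : {self.cot1_fold:.6g}",
        ]
        return "\n".join(lines)
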