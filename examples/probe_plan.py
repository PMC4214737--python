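"""Plan BAC template pooling and probe mass for one hybridization.

Two BAC clones cover a 209.2 kb composite target; template DNA is pooled in
proportion to covered span, and the probe quantity is 2500x the theoretical
mass of target fragments present in a 2 ug library pool.
"""

from catchseq import (
    BacClone,
    HybridizationPlan,
    pool_bac_masses,
)

clones = [BacClone("RP11-A", 150_000), BacClone("RP11-B", 59_200)]
target_size = sum(c.covered_span for c in clones)

masses = pool_bac_masses(clones, total_mass=4.0)  # 4 ug template pool
print("BAC template pool (4 ug total):")
for clone in clones:
    print(f"  {clone.name}: {clone.covered_span/1000:.1f} kb covered "
          f"-> {masses[clone.name]:.2f} ug")

plan = HybridizationPlan(library_mass=2e6, target_size=target_size)
print()
print(plan.report())
print()
print(f"-> each hybridization needs {plan.probe_mass/1e6:.3f} ug of probe; "
      "the theoretical yield is the mass of target fragments expected in "
      "the library before capture.")
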