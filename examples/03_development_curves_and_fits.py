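"""Pan/core development curves and growth-law fits at the genus scale.

Uses the 'guyparkeria-like' preset — eight genomes designed with 1458
core, 909 accessory, and 837 singleton families (pan 3204) — computes
pan and core sizes over every genome subset, and fits Heaps' law
n = k·N^gamma to the pan medians and the exponential decay
n = k·e^(-N/tau) + tg_theta to the core medians.  alpha = 1 - gamma < 1
means the pangenome is open: each added genome keeps contributing genes.
"""

from panbbh import (
    classify_openness,
    development,
    fit_decay,
    fit_heaps,
    partition,
    preset,
    simulate_genome_set,
    table_from_truth,
)

config = preset("guyparkeria-like")
_, truth = simulate_genome_set(config)
table = table_from_truth(truth)

counts = partition(table)
print(f"partition: pan={counts.pan} core={counts.core} "
      f"accessory={counts.accessory} singleton={counts.singleton}")

curve = development(table, seed=0)
print("\n N  median_pan  median_core")
for n in curve.N:
    print(f"{n:>2}  {curve.median_pan[n]:>10.1f}  {curve.median_core[n]:>11.1f}")

heaps = fit_heaps(curve)
decay = fit_decay(curve)
print(f"\nHeaps' law:  n = {heaps.k:.1f} * N^{heaps.gamma:.3f}"
      f"   (alpha = {heaps.alpha:.3f} -> {classify_openness(heaps)} pangenome)")
print(f"core decay:  n = {decay.k:.1f} * e^(-N/{decay.tau:.3f}) + {decay.tg_theta:.1f}")
print("(tg_theta estimates the stable core size as genomes accumulate)")
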