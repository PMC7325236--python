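"""Introduce MCAR, MAR and MNAR missing values and compare what they hit.

Every mechanism masks exactly 3% of the matrix entries; they differ in
which values go missing: MCAR uniformly, MAR according to per-CpG
propensities, MNAR preferentially (70%) inside a chosen beta range.
"""

import numpy as np

from methylbench import CohortConfig, Mechanism, generate_cohort, simulate

x, profile = generate_cohort(CohortConfig(n_samples=50, n_cpgs=2000, seed=3))
overall = x.values.ravel()

print(f"{'mechanism':<10} {'masked':>7} {'<=0.2':>7} {'0.4-0.6':>8} {'>=0.8':>7}")
print(f"{'(overall)':<10} {'-':>7} {np.mean(overall <= 0.2):7.3f} "
      f"{np.mean((overall >= 0.4) & (overall <= 0.6)):8.3f} {np.mean(overall >= 0.8):7.3f}")
for mech in Mechanism:
    md = simulate(x, mech, 0.03, weights=profile, seed=42)
    t = md.truth
    print(f"{mech.value:<10} {len(md.positions):>7} {np.mean(t <= 0.2):7.3f} "
          f"{np.mean((t >= 0.4) & (t <= 0.6)):8.3f} {np.mean(t >= 0.8):7.3f}")

print("\nMCAR mirrors the overall distribution; MAR shifts mass mid-range")
print("(high-propensity CpGs live there); each MNAR variant concentrates ~70%")
print("of the masked values inside its target beta range.")
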