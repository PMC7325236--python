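"""Generate a synthetic methylation cohort and inspect its structure.

The generator draws each CpG from an unmethylated / mid-range /
methylated class (bimodal marginal), adds low-rank inter-sample factors
on the logit scale, and samples Beta noise with concentration kappa, so
variance peaks mid-range.  A high-propensity CpG subset is shifted into
the mid-range and carries most of the baseline missingness weight.
"""

import numpy as np

from methylbench import CohortConfig, apply_baseline_missingness, generate_cohort

cfg = CohortConfig(n_samples=50, n_cpgs=2000, seed=0)
x, profile = generate_cohort(cfg)
v = x.values

print(f"cohort: {x.n_samples} samples x {x.n_cpgs} CpGs, kappa={cfg.kappa}")
print(f"beta mass <=0.1: {np.mean(v <= 0.1):.3f}   [0.45,0.55]: "
      f"{np.mean((v >= 0.45) & (v <= 0.55)):.3f}   >=0.9: {np.mean(v >= 0.9):.3f}")
print("(bimodal: both extremes carry far more mass than the mid bin)")

hi = v[:, profile.high_cpgs]
print(f"high-propensity CpGs in [0.4,0.8]: {np.mean((hi >= 0.4) & (hi <= 0.8)):.3f} "
      f"vs overall {np.mean((v >= 0.4) & (v <= 0.8)):.3f}  (mid-range shifted)")

masked = apply_baseline_missingness(x, profile, overall_rate=0.03, rng_seed=1)
per_cpg = masked.mask.sum(axis=0)
print(f"baseline missingness at 3%: overall {masked.n_missing / v.size:.4f}, "
      f"CpGs missing in >20% of samples: {np.mean(per_cpg > 0.2 * x.n_samples):.3f}")
print("(the high-propensity subset concentrates the missingness, as on real arrays)")
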