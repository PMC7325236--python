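"""Beta-value / M-value conversions on intensities and whole matrices.

The beta-value is the regularized methylated-intensity fraction (offset
alpha=100); the M-value is the regularized log2 intensity ratio (offset
alpha=1).  Ignoring the offsets the two are related by a base-2 logit.
"""

import numpy as np

from methylbench import (
    Scale,
    beta_from_intensities,
    beta_to_m,
    convert_matrix,
    m_from_intensities,
    m_to_beta,
)
from methylbench.matrix import MethylMatrix

meth, unmeth = 1800.0, 600.0
b = beta_from_intensities(meth, unmeth)
m = m_from_intensities(meth, unmeth)
print(f"intensities ({meth:.0f}, {unmeth:.0f}): beta = {b:.4f}, M = {m:.4f}")
print(f"logit link check: m_to_beta(M) = {m_to_beta(m):.4f} (close to beta above;")
print("the small gap is the alpha-offset perturbation, which vanishes for bright probes)")

x = MethylMatrix(
    np.array([[0.5, np.nan], [0.8, 0.2]]),
    sample_ids=["S0", "S1"],
    cpg_ids=["cg0", "cg1"],
    scale=Scale.BETA,
)
xm = convert_matrix(x, Scale.M)
print("\nbeta matrix:\n", x.values)
print("as M-values (missing entries stay missing):\n", xm.values)
back = convert_matrix(xm, Scale.BETA)
print("round-trip max |error|:", np.nanmax(np.abs(back.values - x.values)))
print("beta 0.5 -> M 0, beta 0.8 -> M 2 (log2(0.8/0.2)); NaN marks the missing entry")
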