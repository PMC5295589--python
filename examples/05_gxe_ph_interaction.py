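"""Allele x base-wine-pH interaction for a proton-pump hemizygote pair.

Reconstructs a two-allele experiment across three pH levels (triplicates per
cell built to hit given means and SEs exactly), runs the per-pH pooled t
comparisons and the two-way interaction F test.
"""

import numpy as np
import pandas as pd

from fermqtl import gxe_analysis

# (allele, pH) -> (mean t2 in days, SE), n = 3 replicates per cell
cells = {
    ("GN", 2.8): (7.46, 0.07), ("SB", 2.8): (5.60, 0.06),
    ("GN", 3.0): (5.80, 0.15), ("SB", 3.0): (4.60, 0.16),
    ("GN", 3.3): (5.10, 0.20), ("SB", 3.3): (4.60, 0.01),
}
rows = []
for (allele, ph), (mean, se) in cells.items():
    d = se * np.sqrt(3)
    rows += [(v, allele, ph) for v in (mean - d, mean, mean + d)]
data = pd.DataFrame(rows, columns=["value", "allele", "env"])

res = gxe_analysis(data, trait_name="t2")
print(res.per_env.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(f"\nallele x pH interaction: F = {res.interaction_F:.2f}, "
      f"p = {res.interaction_p:.2g}")
# The SB allele shortens t2 at every pH, but the advantage shrinks from
# ~1.9 days at pH 2.8 (***) to ~0.5 days at pH 3.3 (ns): a significant
# allele-by-environment interaction driven by acid stress.
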