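"""Cross-level statistics from published strain means.

Computes the heterosis index d/m for the five kinetic traits from the
published diploid parent (GN, SB) and hybrid (HO-BN) means, and illustrates
heritability and transgression on a simulated segregant population.
"""

import numpy as np

from fermqtl import heritability, heterosis_dm, transgression

cross_means = {  # trait: (GN, SB, hybrid)
    "Pmax": (5.33, 5.53, 5.37),
    "rate": (0.53, 0.73, 1.30),
    "t0.5": (4.00, 4.00, 3.00),
    "t2": (8.60, 7.10, 5.00),
    "t5": (26.00, 15.00, 13.00),
}
print("trait   d/m")
for trait, (gn, sb, hyb) in cross_means.items():
    print(f"{trait:>5}  {heterosis_dm(hyb, gn, sb):+.3f}")
print("(rate d/m ~ +1.06: the hybrid ferments twice as fast as the mid-parent,")
print(" best-parent heterosis; the time traits are negative because lower = faster)")

rng = np.random.default_rng(1)
segregants = rng.normal(0.63, 0.12, size=117)  # rate-like trait around mid-parent
env_sd = 0.05
h2 = heritability(np.var(segregants, ddof=1), env_sd ** 2)
pct, n = transgression(segregants, p1_mean=0.53, p2_mean=0.73, env_sd=env_sd, k=2.0)
print(f"\nsimulated segregants: H^2 = {h2:.2f}, transgressive {pct:.1f}% ({n}/117)")
# High H^2: replicate noise is small against the segregant spread.
# Transgressive segregants fall outside [0.53, 0.73] by > 2 environmental SDs.
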