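"""Simulate the default F1 cross and genome-scan the strongest trait.

Builds the 16-chromosome yeast cross (1071 markers, 117 segregants), plants
the default three-QTL architecture, scans t5 (time to 5 bar) with the
Wilcoxon rank-sum statistic and a 200-permutation genome-wide threshold, and
prints the significant QTL calls.
"""

import warnings

from fermqtl import (call_qtl, default_architecture, default_genome,
                     permutation_threshold, simulate_cross, simulate_parents,
                     simulate_traits, wilcoxon_scan)

warnings.filterwarnings("ignore", message="n_perm is small")

genome = default_genome()
parents = simulate_parents(genome, n_snps=1071, seed=1)
cross = simulate_cross(parents, n_segregants=117, genome=genome, seed=1)
traits = simulate_traits(cross, default_architecture(), seed=1)

gm = cross.to_genotype_matrix()
y = traits["t5"].to_numpy()
profile = wilcoxon_scan(gm, y, trait_name="t5")
null = permutation_threshold(gm, y, n_perm=200, seed=1, trait_name="t5")

print(f"markers scanned : {int(profile.table['defined'].sum())}")
print(f"max LK          : {profile.max_lk:.2f}")
print(f"5% threshold    : {null.threshold():.2f}  (from {null.n_perm} permutations)")
for q in call_qtl(profile, null):
    print(f"QTL {q.chrom}:{q.peak_pos}  LK={q.peak_lk:.2f}  "
          f"interval {q.start}-{q.end}  beneficial allele: {q.beneficial_parent}")
# The planted t5 locus sits at chrXVI:635000 (49% of trait variance); the
# peak lands within a few markers of it, far above the threshold. A second,
# barely-significant call can appear on an empty chromosome at some seeds -
# that is exactly what a 5% genome-wide (family-wise) error rate permits.
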