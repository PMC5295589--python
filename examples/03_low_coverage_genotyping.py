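"""Genotype segregants from low-coverage reads and build the marker map.

Sequencing each segregant at ~4.5x leaves some sites unread; the count rule
calls a site only when reads support one parental allele unopposed. The map
filter then drops distorted (non-1:1) and sparse markers and thins to one
marker per 15 kb.
"""

from fermqtl import (build_marker_map, call_genotypes, default_genome,
                     simulate_cross, simulate_parents, simulate_reads)

genome = default_genome()
parents = simulate_parents(genome, n_snps=1071, seed=2)
cross = simulate_cross(parents, n_segregants=117, genome=genome, seed=2)
counts = simulate_reads(cross, mean_coverage=4.5, error_rate=0.002, seed=2)

gm = call_genotypes(counts, min_reads=1, max_conflict=0)
missing = (gm.calls == -1).mean()
wrong = ((gm.calls != cross.haplotypes) & (gm.calls != -1)).mean()
print(f"missing cells : {100 * missing:.1f}%   (Poisson depth 0 plus conflicts)")
print(f"wrong calls   : {100 * wrong:.3f}%  (error reads slipping through)")

mapped = build_marker_map(gm, alpha=0.05, max_missing_frac=0.5, spacing_kb=15)
print("marker filters:", mapped.markers["status"].value_counts().to_dict())
# 'pass' markers (one per 15-kb window, 1:1 segregation, callable in >= half
# the progeny) are the ones the genome scan uses.
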