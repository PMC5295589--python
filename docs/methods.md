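# Methods

`fermqtl` reimplements, as a tested library, the quantitative-genetics
analysis of an F1-hybrid yeast cross phenotyped for in-bottle (sparkling-wine
style) second fermentation: kinetic traits from CO2 pressure curves, segregant
genotypes from low-coverage sequencing counts, a nonparametric genome scan
with an empirical genome-wide threshold, and the cross-level statistics that
summarize heterosis, heritability, transgression and QTL architecture. A
synthetic-cross generator with full ground truth makes every stage testable
without external data.

## Kinetic model

Pressure readings taken at the fermentation temperature are expressed at a
10 °C reference through Henry's law with a van 't Hoff temperature factor:

    p_ref = p_obs · exp(K · (1/T_obs − 1/T_ref)),  T in kelvin.

`K` (default 2400 K) is the enthalpy scale of CO2 dissolution in water; it is
exposed as a parameter because published values for the CO2 Henry constant's
temperature slope cluster around 2200–2500 K and the right value for base
wine is not settled. The scaling is multiplicative, so curve shape and the
ordering of threshold-crossing times are preserved.

Each strain × replicate curve is fitted with the five-parameter (Gottschalk)
asymmetric logistic

    P(t) = A + (D − A) / (1 + (t/C)^(−B))^G,

with the lower asymptote `A` fixed at 0 (a freshly sealed bottle holds no
excess pressure; `A` can be freed). Fitting is bounded least squares with a
deterministic multi-start: `D` from the maximum observed pressure, `C` from
the time of half-maximum, `B ∈ {1,2,4}` × `G ∈ {0.5,1,2}`, keeping the best
SSE. Flat curves and fits where no start converges are flagged and excluded
from trait extraction.

Five traits are read off the fitted curve:

| trait | units | definition |
|---|---|---|
| Pmax | bar | upper asymptote `D` |
| rate | bar/day | maximum of the analytic dP/dt over t > 0 |
| t0.5, t2, t5 | days | closed-form inversion of `P(t) = X` |

The derivative maximum has the closed form `u*/(1+u*) = (B+1)/(B(G+1))` and
exists when `B·G > 1`; otherwise the slope is unbounded at t → 0+ and the
rate is reported unavailable. A threshold time is unavailable when `X ≥ D`
(in particular t5 requires a plateau above 5 bar). The derivative-maximum
definition of "rate" was chosen over finite-difference slopes because it is
insensitive to sampling noise; replicates are fitted independently and
per-strain traits are replicate means.

## Genotyping and the marker map

Two homozygous parents called against one reference are reduced to
*distinguishing* sites: kept where exactly one parent differs from the
reference, or both differ with different alternates; shared variants carry no
linkage information and are dropped.

Segregant calls use a count rule on per-site reads: call P1 when
`n_P1 ≥ min_reads` (default 1) and `n_P2 ≤ max_conflict` (default 0),
symmetrically for P2, otherwise missing. At 3–6× coverage this prefers
missingness over wrong calls; both knobs are exposed.

Marker filters, applied in this order:

1. **sparse** — missing in > 50% of segregants (a marker must be callable in
   at least half the progeny to be judged at all);
2. **distorted** — χ² goodness-of-fit against 1:1 on the non-missing calls
   rejects at α = 0.05 (df 1, no continuity correction);
3. **thinned** — within each half-open 15-kb window per chromosome only the
   marker with the fewest missing calls survives (ties → leftmost).

Only `pass` markers feed the scan. Coordinates are 1-based inclusive
throughout.

## Genome scan

At every pass marker the trait is compared between the P1- and P2-inheriting
segregants with a two-sided Mann–Whitney/Wilcoxon rank-sum test;
`LK = −log10 p`. Markers where either group has fewer than `min_group`
(default 10) members get an *undefined* LK — not zero — so they can neither
fire nor deflate thresholds.

p-values: the exact null distribution is used when both groups have ≤ 25
members and the subset is tie-free; otherwise a normal approximation with
continuity and tie corrections, refined by a fourth-moment Edgeworth term.
The exact U null is symmetric and platykurtic with

    γ₂ = −(6/5) · (m² + n² + mn + m + n) / (mn(m+n+1)),

and the refinement `Φ(−z) + φ(z)(γ₂/24)(z³ − 3z)` keeps small-group tail
p-values within ~0.15 log10 units of the exact ones, where the plain normal
is off by up to ~0.4 near the support boundary. The correction is floored at
5% of the plain normal tail so it can never produce negative or badly
non-monotone p-values in the far tail.

Genome-wide significance is empirical: the trait vector is permuted across
segregants (genotypes fixed), the full scan recomputed, and the maximum LK
over defined markers recorded; the threshold is the (1−α) type-7 quantile of
those maxima. The permutation engine is vectorized (one small matrix product
per permutation: pre-ranked traits when the matrix has no missing cells, a
pairwise-comparison matrix otherwise) and always evaluates the approximate
statistic; at the study scale (groups ≈ 58/59) the observed scan resolves to
the identical formula, so observed profile and null are mutually consistent.
Tied traits combined with missing genotypes fall back to a slower per-marker
path, since the subset tie structure then changes per permutation.

QTL calls: per chromosome, local maxima above the threshold become peaks; the
support interval runs to the outermost flanking markers within 1 LK unit of
the peak (the drop is configurable — the convention is this package's own, as
support-interval rules are rarely stated in scan reports); overlapping
intervals merge into the higher peak. The beneficial parent at a peak is the
allele group with the better mean in the trait's natural direction (higher
Pmax/rate, lower tX). Candidate genes are the annotation intervals
overlapping the support interval that carry a parental nonsynonymous SNP.

## Cross-level statistics

* **Heterosis**: d/m = (hybrid − mid-parent)/mid-parent, scale-invariant.
* **Broad-sense heritability**: H² = (V_seg − V_env)/V_seg on segregant
  trait means, with V_env the pooled replicate variance; clamped to [0, 1]
  with a warning. The source literature cites its H² and transgression
  formulas to earlier work without restating them, so these definitions are
  explicit, configurable stand-ins.
* **Transgression**: a segregant is transgressive when it falls strictly
  outside the parental range widened by k·SD_env (k default 2) on each side.
* **Variance decomposition**: sequential (type-I) ANOVA of
  `Y = m + ΣQTLk + ΣQTLj×QTLk + E` at the peak markers, mains first; each
  term's share is its SS over the total SS. Interactions with empty design
  cells are dropped with a warning. The formula interface canonicalizes the
  interaction entry order (QTL1:QTL2, QTL1:QTL3, QTL2:QTL3); in a
  near-balanced cross the interaction blocks are near-orthogonal, so the
  sequential shares are insensitive to that order. Levene (median-centred)
  and Shapiro–Wilk p-values are reported as model diagnostics, not gates.
* **Duncan's multiple range test**: sorted means are compared against
  critical ranges `q(1−(1−α)^(p−1); p, df)·sqrt(MSE/n_h)` (harmonic-mean
  group size), with the containment rule that sub-ranges of a
  non-significant range are non-significant; groups sharing a letter do not
  differ. With two groups this is exactly the pooled t decision.
* **G×E**: per environment a pooled-variance two-sided t test between the
  two allele groups with star tiers (≤0.05 *, ≤0.01 **, ≤0.001 ***), plus a
  two-way allele×environment interaction F test on the full table.

## Synthetic cross generator

The generator's defaults mirror the study design: 16 chromosomes at real
yeast sizes (12.07 Mb total), 0.4 cM/kb, 1071 distinguishing sites placed
uniformly (length-weighted), 117 haploid segregants, sequencing at 4.5× mean
Poisson depth with 0.002 allele-flip error, two replicates per strain.

* **Meiosis**: Haldane model — per chromosome the crossover count is Poisson
  with mean equal to the genetic length in Morgans, breakpoints uniform, no
  interference; starting parent a fair coin. Tetrad structure, gene
  conversion and viability selection are deliberately not modelled.
* **Traits**: additive on the trait scale. Each planted locus shifts its
  trait by a signed allele-substitution effect; an effect explaining a
  target variance share s against residual SD σ is `2σ·sqrt(s/(1−s))`. The
  default architecture plants three point QTL mirroring the mapped loci:
  ~24% of rate on chrVII (P2 allele beneficial), ~14% of t2 on chrIV (P1),
  ~49% of t5 on chrXVI (P1). A separate prebuilt architecture provides a
  linked three-locus block on chrVII with alternating beneficial parents
  (the repulsion-phase configuration behind pseudo-overdominance). Residual
  trait SDs (0.08 bar Pmax, 0.12 bar/d rate, 0.3/0.8/1.5 d for t0.5/t2/t5)
  are chosen to give parental separations and segregant spreads of the order
  the study reports.
* **Curves**: per strain a 5PL curve is solved (in log-parameter space)
  whose analytic traits match the genetically targeted ones — Pmax maps to D
  directly and (C, B, G) are solved against up to three rate/threshold
  targets, the remainder pinned to a reference curve shape. The *achieved*
  analytic traits of the solved curve are recorded as ground truth (for the
  default architecture they equal the targets to ~1e−9; inconsistent target
  combinations, possible in extreme noise draws, are resolved by least
  squares rather than by failing). Curves are then un-normalized to the
  16 °C observation scale and sampled with Normal(0, 0.05 bar) replicate
  noise, so the kinetics stage genuinely exercises the normalization.
* **Hybrid**: purely additive, i.e. at the mid-parent value. Real heterosis
  needs dominance or repulsion-phase linkage; the generator does not add
  dominance, so synthetic d/m ≈ 0 — passing pipeline tests therefore shows
  the statistics are computed correctly, not that the generator reproduces
  heterosis itself.
* Randomness flows from one master seed through named substreams
  (parents/cross/reads/phenotypes/permutations), so each stage is
  independently reproducible.

## Problem sizes and calibration checks

The test suite verifies, at the study scale of 117 segregants × 1071
markers: family-wise error of the permutation threshold 0.05 ± 0.025 over
500 null crosses (200 permutations each); exact-enumeration agreement of the
scan's p-values for all group sizes ≤ 8; genotyping closure (error-free deep
reads reproduce the true haplotypes exactly, and the 1:1 χ² filter flags
~4–5% of markers under the null, matching the exact discrete rate at
n = 117); 5PL round trips to 1e−6; and a planted 30%-share ANOVA recovered
to ±2 points at n = 5000.

Detection power is a real limitation worth stating plainly: a locus
explaining ~14% of its trait in 117 segregants has an expected rank-sum z of
~4.0 against a 1071-marker genome-wide threshold of z ≈ 3.8–3.9, i.e. ~50%
power. The package's recovery benchmark reflects that — the two strong
planted loci (24%, 49%) are recovered essentially always, the 14% locus in
about half of seeded runs, so a joint all-three-loci benchmark lands near
50%, not near certainty. This mirrors the underlying study, whose scan also
did not detect the ~14% QTL acting on t2.

## Known limitations

* The generator's genetic map (uniform 0.4 cM/kb) is a stand-in; real maps
  have hot/cold spots, and the true map of the original cross is not public.
* No dominance, epistasis (beyond what linked blocks induce), or G×E in the
  synthetic phenotypes; the G×E statistics are exercised on reconstructed
  summary data instead.
* The Edgeworth-refined approximation is derived for tie-free data; with
  heavy ties it degrades toward the plain tie-corrected normal.
* Heritability/transgression formulas are the package's explicit choices
  (see above), not a reproduction of an external formula.
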