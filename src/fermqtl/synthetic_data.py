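"""Synthetic F1 cross with known ground truth.

Emulates the study design end to end: two fully homozygous parental strains
(P1, P2) differing at ~1071 biallelic sites over the 16 yeast chromosomes, a
population of 117 haploid segregants produced by meiosis (Haldane crossover
model, no interference), low-coverage whole-genome sequencing of each
segregant (Poisson depth, small allele-flip error), and 5PL-shaped second
fermentation kinetics whose traits carry planted additive QTL effects. Every
stage records its ground truth so downstream genotype calls, genome scans and
variance decompositions have a recoverable answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .genotyping import MISSING, P1, P2, AlleleCountTable, GenotypeMatrix  # noqa: F401
from .kinetics import (REF_PARAMS, TRAIT_DIRECTIONS, normalize_pressure, pl5,
                       solve_params_for_traits, traits_from_params)

__all__ = [
    "GenomeModel", "Locus", "QtlArchitecture", "TrueCross", "MeasurementDesign",
    "SimulatedPhenotypes", "default_genome", "default_architecture",
    "pseudo_overdominance_architecture", "effect_for_share",
    "simulate_parents", "simulate_cross", "simulate_reads",
    "simulate_traits", "parental_trait_values", "resolve_loci", "simulate_phenotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus a uniform genetic-map density (cM per kb)."""

    chromosomes: tuple[tuple[str, int], ...]
    cm_per_kb: float = 0.4

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.cm_per_kb < 0:
            raise ValueError("cm_per_kb must be >= 0")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([length for _, length in self.chromosomes], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())


#: sacCer3 chromosome sizes (bp) - a 16-chromosome, ~12.07 Mb genome.
_SACCER3 = (
    ("chrI", 230218), ("chrII", 813184), ("chrIII", 316620), ("chrIV", 1531933),
    ("chrV", 576874), ("chrVI", 270161), ("chrVII", 1090940), ("chrVIII", 562643),
    ("chrIX", 439888), ("chrX", 745751), ("chrXI", 666816), ("chrXII", 1078177),
    ("chrXIII", 924431), ("chrXIV", 784333), ("chrXV", 1091291), ("chrXVI", 948066),
)


def default_genome(cm_per_kb: float = 0.4) -> GenomeModel:
    """The 16-chromosome budding-yeast genome at ~0.4 cM/kb."""
    return GenomeModel(chromosomes=_SACCER3, cm_per_kb=cm_per_kb)


def effect_for_share(share: float, noise_sd: float) -> float:
    """Additive allele-substitution effect giving a target variance share.

    For a balanced biallelic locus (allele indicator with variance 1/4) and
    residual trait SD ``noise_sd``, an effect beta yields share
    s = (beta^2/4) / (beta^2/4 + noise_sd^2); inverting gives
    beta = 2 * noise_sd * sqrt(s / (1 - s)).
    """
    if not 0 < share < 1:
        raise ValueError("share must be in (0, 1)")
    return 2.0 * noise_sd * float(np.sqrt(share / (1.0 - share)))


@dataclass(frozen=True)
class Locus:
    """One planted QTL: position, affected trait, effect size, beneficial parent.

    ``effect`` is the magnitude (trait units) of the P1-vs-P2 allele
    substitution; ``beneficial`` names the parent whose allele makes the trait
    *better* in its natural direction (higher Pmax/rate, lower tX).
    """

    chrom: str
    pos: int
    trait: str
    effect: float
    beneficial: str = "P2"

    def __post_init__(self):
        if not np.isfinite(self.effect) or self.effect < 0:
            raise ValueError("effect must be finite and non-negative")
        if self.beneficial not in ("P1", "P2"):
            raise ValueError("beneficial parent must be 'P1' or 'P2'")
        if self.trait not in TRAIT_DIRECTIONS:
            raise ValueError(f"unknown trait {self.trait!r}")

    @property
    def delta_p2(self) -> float:
        """Trait shift of the P2 allele relative to P1 (signed, trait units)."""
        sign = 1.0 if self.beneficial == "P2" else -1.0
        return sign * TRAIT_DIRECTIONS[self.trait] * self.effect


_DEFAULT_NOISE = {"Pmax": 0.08, "rate": 0.12, "t0.5": 0.3, "t2": 0.8, "t5": 1.5}


def _reference_baseline() -> dict[str, float]:
    tv = traits_from_params(REF_PARAMS["d"], REF_PARAMS["c"], REF_PARAMS["b"], REF_PARAMS["g"])
    return tv.as_dict()


@dataclass
class QtlArchitecture:
    """Planted genetic architecture: loci, optional linked block, noise levels.

    ``baseline`` holds the population-mean trait values (defaults to the
    traits of the reference 5PL curve); ``noise_sd`` the residual genetic /
    environmental trait SDs; ``replicate_sd`` the pressure observation noise
    (bar) applied when curves are sampled.
    """

    loci: list[Locus] = field(default_factory=list)
    linked_block: list[Locus] | None = None
    baseline: dict[str, float] = field(default_factory=_reference_baseline)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    replicate_sd: float = 0.05

    def __post_init__(self):
        if any(sd < 0 for sd in self.noise_sd.values()) or self.replicate_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.linked_block is not None:
            if len(self.linked_block) < 2:
                raise ValueError("a linked block needs at least 2 loci")
            if len({loc.chrom for loc in self.linked_block}) != 1:
                raise ValueError("linked-block loci must share one chromosome")

    @property
    def all_loci(self) -> list[Locus]:
        return list(self.loci) + list(self.linked_block or [])

    @property
    def affected_traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.all_loci:
            seen.setdefault(loc.trait, None)
        return list(seen)

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = dict(genome.chromosomes)
        for loc in self.all_loci:
            if loc.chrom not in lengths:
                raise ValueError(f"locus chromosome {loc.chrom!r} not in genome")
            if not 1 <= loc.pos <= lengths[loc.chrom]:
                raise ValueError(f"locus {loc.chrom}:{loc.pos} outside chromosome")


def default_architecture() -> QtlArchitecture:
    """Three point QTL mirroring the study's mapped loci.

    Variance shares ~24% (rate, chrVII, P2 allele beneficial), ~14% (t2,
    chrIV, P1 beneficial) and ~49% (t5, chrXVI, P1 beneficial) at the default
    residual trait SDs.
    """
    return QtlArchitecture(loci=[
        Locus("chrVII", 570_000, "rate", effect_for_share(0.24, _DEFAULT_NOISE["rate"]), "P2"),
        Locus("chrIV", 571_000, "t2", effect_for_share(0.14, _DEFAULT_NOISE["t2"]), "P1"),
        Locus("chrXVI", 635_000, "t5", effect_for_share(0.49, _DEFAULT_NOISE["t5"]), "P1"),
    ])


def pseudo_overdominance_architecture() -> QtlArchitecture:
    """A linked three-gene block with alternating beneficial parents.

    Emulates a single chromosome-VII region where two loci favour the P2
    allele and the middle-distance third favours P1, all acting on t2 - the
    repulsion-phase configuration that produces apparent overdominance in the
    hybrid and strong transgression among segregants.
    """
    sd = _DEFAULT_NOISE["t2"]
    block = [
        Locus("chrVII", 545_000, "t2", effect_for_share(0.04, sd), "P2"),
        Locus("chrVII", 565_000, "t2", effect_for_share(0.35, sd), "P2"),
        Locus("chrVII", 590_000, "t2", effect_for_share(0.09, sd), "P1"),
    ]
    loci = [Locus("chrXVI", 635_000, "t5", effect_for_share(0.49, _DEFAULT_NOISE["t5"]), "P1")]
    return QtlArchitecture(loci=loci, linked_block=block)


@dataclass
class TrueCross:
    """Ground truth of a simulated cross.

    ``haplotypes`` is (n_segregants, n_markers) with 0 = P1 allele inherited,
    1 = P2; ``crossovers`` maps segregant -> chromosome -> sorted breakpoint
    positions (bp).
    """

    variants: pd.DataFrame
    segregants: list[str]
    haplotypes: np.ndarray
    crossovers: dict[str, dict[str, np.ndarray]]

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.segregants), len(self.variants)):
            raise ValueError("haplotypes shape does not match segregants x markers")
        if not np.isin(self.haplotypes, (P1, P2)).all():
            raise ValueError("haplotype codes must be P1/P2")

    def to_genotype_matrix(self) -> GenotypeMatrix:
        """Perfect (error-free, fully observed) genotype calls."""
        return GenotypeMatrix(calls=self.haplotypes.copy(),
                              segregants=list(self.segregants),
                              markers=self.variants[["chrom", "pos"]].copy())


def simulate_parents(genome: GenomeModel, n_snps: int, seed: int) -> pd.DataFrame:
    """Distinguishing biallelic sites between two homozygous parents.

    Sites are placed uniformly, chromosomes weighted by physical length, with
    unique (chrom, pos); each site gets distinct P1/P2 alleles. The reference
    base matches one parent most of the time (either with equal odds) and is
    occasionally a third allele, as with two strains both far from the
    reference assembly.
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if n_snps > genome.total_length:
        raise ValueError("more SNPs requested than genome positions")
    rng = substream(seed, "parents")
    names = genome.names
    lengths = genome.lengths
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=n_snps, p=probs)
    counts = np.bincount(chrom_idx, minlength=len(names))

    recs = []
    for ci, name in enumerate(names):
        want = int(counts[ci])
        pos: np.ndarray = np.empty(0, dtype=np.int64)
        while len(pos) < want:
            extra = rng.integers(1, lengths[ci] + 1, size=want - len(pos) + 8)
            pos = np.unique(np.concatenate([pos, extra]))[: want] if len(pos) else \
                np.unique(extra)[: want]
        for p in np.sort(pos[:want]):
            recs.append((name, int(p)))
    # alleles: draw an ordered pair of distinct bases per site
    first = rng.integers(0, 4, size=n_snps)
    second = (first + rng.integers(1, 4, size=n_snps)) % 4
    ref_pick = rng.random(n_snps)
    rows = []
    for k, (name, p) in enumerate(recs):
        p1a, p2a = _BASES[first[k]], _BASES[second[k]]
        if ref_pick[k] < 0.45:
            ref = p1a
        elif ref_pick[k] < 0.90:
            ref = p2a
        else:
            others = [b for b in "ACGT" if b not in (p1a, p2a)]
            ref = others[int(ref_pick[k] * 1e6) % len(others)]
        rows.append((name, p, ref, p1a, p2a))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "p1_allele", "p2_allele"])
    key = {c: i for i, c in enumerate(names)}
    return (df.assign(_k=df["chrom"].map(key)).sort_values(["_k", "pos"], kind="mergesort")
            .drop(columns="_k").reset_index(drop=True))


def simulate_cross(parents: pd.DataFrame, n_segregants: int, genome: GenomeModel,
                   seed: int) -> TrueCross:
    """Meiotic haplotypes for a population of haploid segregants.

    Per segregant and chromosome, the crossover count is Poisson with mean
    equal to the chromosome's genetic length in Morgans
    (length_kb * cm_per_kb / 100) and breakpoints are uniform - the Haldane
    no-interference model. The starting parent is a fair coin and the
    haplotype alternates at each breakpoint.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    rng = substream(seed, "cross")
    seg_names = [f"seg{i + 1:03d}" for i in range(n_segregants)]
    hap = np.zeros((n_segregants, len(parents)), dtype=np.int8)
    xovers: dict[str, dict[str, np.ndarray]] = {s: {} for s in seg_names}
    chrom_arr = parents["chrom"].to_numpy()
    pos_arr = parents["pos"].to_numpy()
    for name, length in genome.chromosomes:
        cols = np.nonzero(chrom_arr == name)[0]
        mpos = pos_arr[cols]
        morgans = (length / 1000.0) * genome.cm_per_kb / 100.0
        n_xo = rng.poisson(morgans, size=n_segregants)
        starts = rng.integers(0, 2, size=n_segregants)
        for i in range(n_segregants):
            xo = np.sort(rng.uniform(0.0, length, size=n_xo[i]))
            xovers[seg_names[i]][name] = xo
            if len(cols):
                hap[i, cols] = (starts[i] + np.searchsorted(xo, mpos)) % 2
    return TrueCross(variants=parents.reset_index(drop=True), segregants=seg_names,
                     haplotypes=hap, crossovers=xovers)


def simulate_reads(cross: TrueCross, mean_coverage: float, error_rate: float,
                   seed: int) -> AlleleCountTable:
    """Low-coverage sequencing counts at every marker site.

    Depth per segregant x site is Poisson(mean_coverage); each read supports
    the true parental allele with probability 1 - error_rate and the other
    parental allele otherwise.
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = substream(seed, "reads")
    depth = rng.poisson(mean_coverage, size=cross.haplotypes.shape)
    n_true = rng.binomial(depth, 1.0 - error_rate)
    n_false = depth - n_true
    is_p1 = cross.haplotypes == P1
    n_p1 = np.where(is_p1, n_true, n_false)
    return AlleleCountTable(variants=cross.variants.copy(),
                            segregants=list(cross.segregants),
                            n_p1=n_p1, n_p2=depth - n_p1,
                            n_other=np.zeros_like(depth))


def resolve_loci(cross: TrueCross, arch: QtlArchitecture) -> pd.DataFrame:
    """Map each planted locus to its nearest simulated marker.

    Returns one row per locus: chrom, pos (truth), trait, effect, beneficial,
    marker index / position. Raises when a locus sits on a marker-free
    chromosome.
    """
    chrom_arr = cross.variants["chrom"].to_numpy()
    pos_arr = cross.variants["pos"].to_numpy()
    rows = []
    for loc in arch.all_loci:
        cols = np.nonzero(chrom_arr == loc.chrom)[0]
        if len(cols) == 0:
            raise ValueError(f"no marker on {loc.chrom} to anchor locus at {loc.pos}")
        j = cols[int(np.argmin(np.abs(pos_arr[cols] - loc.pos)))]
        rows.append({"chrom": loc.chrom, "pos": loc.pos, "trait": loc.trait,
                     "effect": loc.effect, "beneficial": loc.beneficial,
                     "delta_p2": loc.delta_p2,
                     "marker_index": int(j), "marker_pos": int(pos_arr[j])})
    return pd.DataFrame(rows)


def simulate_traits(cross: TrueCross, arch: QtlArchitecture, seed: int) -> pd.DataFrame:
    """Genetic trait values per segregant: baseline + planted effects + noise.

    Each locus adds ``delta_p2 * (g - 1/2)`` with g the inherited allele
    (0 = P1, 1 = P2), so the baseline is the population mean; independent
    Normal(0, noise_sd) residuals are then added per trait.
    """
    arch_loci = resolve_loci(cross, arch)
    rng = substream(seed, "phenotypes")
    n = len(cross.segregants)
    out = pd.DataFrame({"segregant": cross.segregants})
    for trait, base in arch.baseline.items():
        vals = np.full(n, float(base))
        for row in arch_loci.itertuples(index=False):
            if row.trait == trait:
                g = cross.haplotypes[:, row.marker_index].astype(float)
                vals += row.delta_p2 * (g - 0.5)
        vals += rng.normal(0.0, arch.noise_sd.get(trait, 0.0), size=n)
        out[trait] = vals
    return out


def parental_trait_values(arch: QtlArchitecture) -> pd.DataFrame:
    """Noise-free genetic trait values of the parents and their F1 hybrid.

    Under the purely additive model the hybrid sits at the mid-parent value;
    heterosis in real crosses needs dominance or linked repulsion-phase loci,
    which this generator does not add to the hybrid itself.
    """
    rows = {}
    for strain, gval in (("P1", 0.0), ("P2", 1.0), ("HYBRID", 0.5)):
        vals = dict(arch.baseline)
        for loc in arch.all_loci:
            vals[loc.trait] += loc.delta_p2 * (gval - 0.5)
        rows[strain] = vals
    return pd.DataFrame(rows).T.rename_axis("strain").reset_index()


@dataclass
class MeasurementDesign:
    """When and how the synthetic bottles are read."""

    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 41.0, 1.0))
    thresholds: tuple[float, ...] = (0.5, 2.0, 5.0)
    temperature_c: float = 16.0
    t_ref_c: float = 10.0
    vant_hoff_k: float = 2400.0
    n_replicates: int = 2


@dataclass
class SimulatedPhenotypes:
    """Output bundle of :func:`simulate_phenotypes`."""

    curves: pd.DataFrame
    traits: pd.DataFrame
    params: dict[str, dict[str, float]]
    loci: pd.DataFrame


def simulate_phenotypes(cross: TrueCross, arch: QtlArchitecture,
                        design: MeasurementDesign | None = None,
                        seed: int = 0) -> SimulatedPhenotypes:
    """Kinetic curves plus ground-truth traits for segregants, parents, hybrid.

    Per strain a genetic trait target is drawn (:func:`simulate_traits`), a
    5PL curve matching the targeted traits is synthesized
    (:func:`~fermqtl.kinetics.solve_params_for_traits`), its *achieved*
    analytic traits are recorded as ground truth, and each replicate is
    sampled at the design times on the observation-temperature scale with
    Normal(0, replicate_sd) pressure noise.
    """
    if design is None:
        design = MeasurementDesign()
    if np.any(np.asarray(design.times) < 0):
        raise ValueError("design times must be non-negative")
    targets = simulate_traits(cross, arch, seed)
    parents = parental_trait_values(arch)
    all_targets = pd.concat([targets.assign(role="segregant"),
                             parents.rename(columns={"strain": "segregant"})
                                    .assign(role=["parent", "parent", "hybrid"])],
                            ignore_index=True)
    constrained = set(arch.affected_traits) | {"Pmax"}

    rng = substream(seed, "replicates")
    factor = float(np.exp(design.vant_hoff_k *
                          (1.0 / (design.temperature_c + 273.15) -
                           1.0 / (design.t_ref_c + 273.15))))
    curve_rows = []
    truth_rows = []
    params_by_strain: dict[str, dict[str, float]] = {}
    times = np.asarray(design.times, dtype=float)
    for row in all_targets.to_dict("records"):
        strain = row["segregant"]
        goal = {t: float(row[t]) for t in constrained}
        params, achieved = solve_params_for_traits(goal)
        params_by_strain[strain] = params
        truth = {"strain": strain, "role": row["role"]}
        truth.update(achieved)
        truth.update({f"target_{k}": v for k, v in goal.items()})
        truth_rows.append(truth)
        p_norm = pl5(times, params["d"], params["c"], params["b"], params["g"])
        for rep in range(1, design.n_replicates + 1):
            noise = rng.normal(0.0, arch.replicate_sd, size=len(times))
            p_obs = np.maximum(p_norm / factor + noise, 0.0)
            for t, p in zip(times, p_obs):
                curve_rows.append((strain, rep, float(t), float(p), design.temperature_c))
    curves = pd.DataFrame(curve_rows, columns=["strain", "replicate", "time_days",
                                               "pressure_bar", "temperature_C"])
    traits = pd.DataFrame(truth_rows)
    return SimulatedPhenotypes(curves=curves, traits=traits, params=params_by_strain,
                               loci=resolve_loci(cross, arch))
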