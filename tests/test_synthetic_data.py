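"""Synthetic cross generator: parents, meiosis, reads, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from fermqtl.kinetics import pl5
from fermqtl.synthetic_data import (GenomeModel, Locus, MeasurementDesign,
                                    QtlArchitecture, default_architecture,
                                    default_genome, effect_for_share,
                                    parental_trait_values, simulate_cross,
                                    simulate_parents, simulate_phenotypes,
                                    simulate_reads, simulate_traits)


class TestGenome:
    def test_default_genome_dimensions(self):
        g = default_genome()
        assert len(g.chromosomes) == 16
        assert g.total_length == pytest.approx(12.07e6, rel=0.01)

    def test_invalid_genomes_rejected(self):
        with pytest.raises(ValueError):
            GenomeModel(chromosomes=(("c1", 100), ("c1", 200)))
        with pytest.raises(ValueError):
            GenomeModel(chromosomes=(("c1", 0),))
        with pytest.raises(ValueError):
            GenomeModel(chromosomes=(("c1", 100),), cm_per_kb=-1.0)


class TestSimulateParents:
    def test_construction_contract(self, yeast_genome):
        p = simulate_parents(yeast_genome, 1071, seed=1)
        assert len(p) == 1071
        assert not p.duplicated(subset=["chrom", "pos"]).any()
        assert (p["p1_allele"] != p["p2_allele"]).all()
        # sorted by genome order, positions within chromosome bounds
        lengths = dict(yeast_genome.chromosomes)
        assert ((p["pos"] >= 1) & (p["pos"] <= p["chrom"].map(lengths))).all()

    def test_empty_and_oversized(self, small_genome):
        assert len(simulate_parents(small_genome, 0, seed=1)) == 0
        with pytest.raises(ValueError):
            simulate_parents(small_genome, small_genome.total_length + 1, seed=1)

    def test_same_seed_is_byte_identical(self, yeast_genome):
        a = simulate_parents(yeast_genome, 200, seed=5)
        b = simulate_parents(yeast_genome, 200, seed=5)
        assert a.to_csv() == b.to_csv()
        c = simulate_parents(yeast_genome, 200, seed=6)
        assert a.to_csv() != c.to_csv()


class TestSimulateCross:
    def test_zero_recombination_limit(self, small_genome):
        g = GenomeModel(chromosomes=small_genome.chromosomes, cm_per_kb=0.0)
        parents = simulate_parents(g, 120, seed=2)
        cross = simulate_cross(parents, 40, g, seed=2)
        for chrom in g.names:
            cols = (parents["chrom"] == chrom).to_numpy()
            block = cross.haplotypes[:, cols]
            assert np.all((block.min(axis=1) == block.max(axis=1)))

    def test_mendelian_allele_frequencies(self, study_cross):
        """Binomial(117, 1/2) puts ~99.9% of markers inside [0.35, 0.65]."""
        _, cross = study_cross
        freq = cross.haplotypes.mean(axis=0)
        assert (np.abs(freq - 0.5) <= 0.15).mean() >= 0.99
        assert abs(freq.mean() - 0.5) < 0.02

    def test_haldane_recombinant_fraction(self):
        """Two markers 15 kb apart at 0.4 cM/kb: r = (1 - exp(-0.12)) / 2."""
        g = GenomeModel(chromosomes=(("chrA", 100_000),), cm_per_kb=0.4)
        parents = pd.DataFrame({"chrom": ["chrA", "chrA"], "pos": [40_000, 55_000],
                                "ref": ["A", "A"], "p1_allele": ["A", "A"],
                                "p2_allele": ["G", "G"]})
        cross = simulate_cross(parents, 5000, g, seed=3)
        rec = (cross.haplotypes[:, 0] != cross.haplotypes[:, 1]).mean()
        r = 0.5 * (1.0 - np.exp(-2 * 0.06))
        se = np.sqrt(r * (1 - r) / 5000)
        assert abs(rec - r) <= 3 * se

    def test_crossovers_sorted_and_deterministic(self, small_genome):
        parents = simulate_parents(small_genome, 50, seed=4)
        a = simulate_cross(parents, 10, small_genome, seed=9)
        b = simulate_cross(parents, 10, small_genome, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        for seg in a.segregants:
            for chrom, xo in a.crossovers[seg].items():
                assert np.all(np.diff(xo) >= 0)


class TestSimulateReads:
    def test_zero_coverage_gives_zero_counts(self, study_cross):
        _, cross = study_cross
        counts = simulate_reads(cross, 0.0, 0.01, seed=1)
        assert counts.n_p1.sum() == 0 and counts.n_p2.sum() == 0

    def test_poisson_depth_zero_fraction(self):
        g = GenomeModel(chromosomes=(("chrA", 2_000_000),), cm_per_kb=0.4)
        parents = simulate_parents(g, 1000, seed=7)
        cross = simulate_cross(parents, 100, g, seed=7)  # 1e5 cells
        counts = simulate_reads(cross, 5.0, 0.0, seed=7)
        depth = counts.n_p1 + counts.n_p2
        frac0 = (depth == 0).mean()
        p0 = np.exp(-5.0)
        se = np.sqrt(p0 * (1 - p0) / depth.size)
        assert abs(frac0 - p0) <= 3 * se

    def test_no_error_reads_match_haplotype(self, study_cross):
        _, cross = study_cross
        counts = simulate_reads(cross, 4.5, 0.0, seed=2)
        assert counts.n_p2[cross.haplotypes == 0].sum() == 0
        assert counts.n_p1[cross.haplotypes == 1].sum() == 0

    def test_same_seed_identical(self, study_cross):
        _, cross = study_cross
        a = simulate_reads(cross, 4.5, 0.002, seed=5)
        b = simulate_reads(cross, 4.5, 0.002, seed=5)
        assert np.array_equal(a.n_p1, b.n_p1) and np.array_equal(a.n_p2, b.n_p2)


class TestSimulateTraits:
    def test_planted_effect_recovered(self):
        """mean(trait | P2) - mean(trait | P1) at the planted marker ~ delta."""
        g = default_genome()
        parents = simulate_parents(g, 300, seed=8)
        cross = simulate_cross(parents, 1000, g, seed=8)
        arch = default_architecture()
        traits = simulate_traits(cross, arch, seed=8)
        loc = [l for l in arch.loci if l.trait == "rate"][0]
        cols = (parents["chrom"] == loc.chrom).to_numpy()
        j = np.nonzero(cols)[0][np.argmin(np.abs(parents.loc[cols, "pos"] - loc.pos))]
        gvec = cross.haplotypes[:, j]
        diff = traits["rate"][gvec == 1].mean() - traits["rate"][gvec == 0].mean()
        se = arch.noise_sd["rate"] * np.sqrt(4.0 / 1000)
        assert abs(diff - loc.delta_p2) <= 3 * se

    def test_no_effects_no_noise_identical_values(self, study_cross):
        _, cross = study_cross
        arch = QtlArchitecture(loci=[], noise_sd={t: 0.0 for t in
                                                  ("Pmax", "rate", "t0.5", "t2", "t5")})
        traits = simulate_traits(cross, arch, seed=1)
        for t in ("Pmax", "rate", "t2"):
            assert traits[t].nunique() == 1

    def test_variance_share_calibration(self):
        beta = effect_for_share(0.49, 1.5)
        share = (beta ** 2 / 4) / (beta ** 2 / 4 + 1.5 ** 2)
        assert share == pytest.approx(0.49, rel=1e-12)


class TestSimulatePhenotypes:
    def test_ground_truth_t2_self_consistency(self, small_genome):
        parents = simulate_parents(small_genome, 60, seed=3)
        cross = simulate_cross(parents, 8, small_genome, seed=3)
        arch = QtlArchitecture(loci=[Locus("chrA", 200_000, "t2", 0.6, "P1")])
        phen = simulate_phenotypes(cross, arch, MeasurementDesign(), seed=3)
        for row in phen.traits.to_dict("records"):
            par = phen.params[row["strain"]]
            root = brentq(lambda t: pl5(t, par["d"], par["c"], par["b"], par["g"]) - 2.0,
                          1e-9, 200.0, xtol=1e-12)
            assert abs(row["t2"] - root) < 1e-6

    def test_no_variation_gives_identical_curves(self, small_genome):
        parents = simulate_parents(small_genome, 40, seed=4)
        cross = simulate_cross(parents, 6, small_genome, seed=4)
        arch = QtlArchitecture(loci=[], noise_sd={t: 0.0 for t in
                                                  ("Pmax", "rate", "t0.5", "t2", "t5")},
                               replicate_sd=0.0)
        phen = simulate_phenotypes(cross, arch, MeasurementDesign(n_replicates=1), seed=4)
        seg = phen.curves[phen.curves["strain"].str.startswith("seg")]
        pivot = seg.pivot_table(index="time_days", columns="strain",
                                values="pressure_bar")
        assert np.allclose(pivot.to_numpy(), pivot.to_numpy()[:, [0]])

    def test_curves_round_trip_through_normalization(self, small_genome):
        """Stored 16 C readings recover the reference-scale curve exactly."""
        from fermqtl.kinetics import normalize_pressure

        parents = simulate_parents(small_genome, 40, seed=5)
        cross = simulate_cross(parents, 3, small_genome, seed=5)
        arch = QtlArchitecture(replicate_sd=0.0)
        phen = simulate_phenotypes(cross, arch, MeasurementDesign(n_replicates=1), seed=5)
        one = phen.curves[(phen.curves["strain"] == "seg001")
                          & (phen.curves["replicate"] == 1)].sort_values("time_days")
        par = phen.params["seg001"]
        back = normalize_pressure(one["pressure_bar"].to_numpy(),
                                  one["temperature_C"].to_numpy(), 10.0, 2400.0)
        truth = pl5(one["time_days"].to_numpy(), par["d"], par["c"], par["b"], par["g"])
        assert np.allclose(back, truth, atol=1e-9)

    def test_parental_values_bracket_hybrid(self):
        arch = default_architecture()
        pv = parental_trait_values(arch).set_index("strain")
        for t in ("rate", "t2", "t5"):
            lo, hi = sorted([pv.loc["P1", t], pv.loc["P2", t]])
            assert lo <= pv.loc["HYBRID", t] <= hi

    def test_negative_design_times_rejected(self, small_genome):
        parents = simulate_parents(small_genome, 40, seed=6)
        cross = simulate_cross(parents, 3, small_genome, seed=6)
        design = MeasurementDesign(times=np.array([-1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_phenotypes(cross, default_architecture(), design, seed=6)
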