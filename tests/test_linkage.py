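"""Linkage: rank-sum scan, permutation thresholds, QTL calling, candidates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, rankdata

from conftest import one_marker_gm
from fermqtl.genotyping import GenotypeMatrix
from fermqtl.linkage import (LinkageProfile, PermutationNull, QtlCall, call_qtl,
                             candidate_genes, permutation_threshold, wilcoxon_scan)
from fermqtl.synthetic_data import simulate_traits


def brute_force_two_sided_p(x_p1, x_p2):
    """Exact rank-sum p by enumerating every group assignment (no ties)."""
    combined = np.concatenate([x_p1, x_p2])
    ranks = rankdata(combined)
    n2 = len(x_p2)
    obs = ranks[len(x_p1):].sum()
    mu = n2 * (len(combined) + 1) / 2.0
    idx = np.array(list(itertools.combinations(range(len(combined)), n2)))
    sums = ranks[idx].sum(axis=1)
    return float((np.abs(sums - mu) >= np.abs(obs - mu) - 1e-9).mean())


class TestWilcoxonScan:
    def test_exact_enumeration_example(self):
        """Groups {1,2,3} vs {4,5,6}: two-sided p = 2/20 = 0.1, LK = 1."""
        gm = one_marker_gm(3, 3)
        prof = wilcoxon_scan(gm, np.array([1.0, 2, 3, 4, 5, 6]), min_group=3)
        row = prof.table.iloc[0]
        assert row["p"] == pytest.approx(0.1, rel=1e-9)
        assert row["lk"] == pytest.approx(1.0, rel=1e-9)

    def test_identical_group_values_give_lk_zero(self):
        gm = one_marker_gm(4, 4)
        prof = wilcoxon_scan(gm, np.array([2.0, 2, 2, 2, 2, 2, 2, 2]), min_group=4,
                             method="approx")
        assert prof.table.iloc[0]["p"] == pytest.approx(1.0)
        assert prof.table.iloc[0]["lk"] == pytest.approx(0.0)

    def test_small_group_markers_undefined_not_zero(self):
        gm = one_marker_gm(3, 17)
        prof = wilcoxon_scan(gm, np.arange(20.0), min_group=10)
        assert not prof.table.iloc[0]["defined"]
        assert np.isnan(prof.table.iloc[0]["lk"])

    def test_monotone_transform_invariance(self, study_cross):
        """A rank test cannot see strictly monotone trait transforms."""
        _, cross = study_cross
        gm = cross.to_genotype_matrix()
        rng = np.random.default_rng(12)
        y = rng.normal(size=117)
        a = wilcoxon_scan(gm, y)
        b = wilcoxon_scan(gm, np.exp(y))
        assert np.allclose(a.table["lk"], b.table["lk"], equal_nan=True)

    def test_exact_vs_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for m, n in [(3, 4), (5, 5), (6, 8), (8, 8)]:
            gm = one_marker_gm(m, n)
            y = rng.normal(size=m + n)
            prof = wilcoxon_scan(gm, y, min_group=2, method="exact")
            oracle = brute_force_two_sided_p(y[:m], y[m:])
            assert prof.table.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)


class TestPermutationThreshold:
    def test_determinism_and_alpha_monotonicity(self, study_cross):
        _, cross = study_cross
        gm = cross.to_genotype_matrix()
        y = np.random.default_rng(1).normal(size=117)
        with pytest.warns(UserWarning):
            a = permutation_threshold(gm, y, n_perm=100, seed=3)
            b = permutation_threshold(gm, y, n_perm=100, seed=3)
        assert a.threshold() == b.threshold()
        assert np.array_equal(a.max_lk, b.max_lk)
        assert a.threshold(0.01) >= a.threshold(0.05)

    def test_genotype_vs_phenotype_permutation_nulls_agree(self, study_cross):
        """Shuffling genotypes instead of the phenotype yields the same
        null max-LK distribution (both break the trait-genotype link)."""
        _, cross = study_cross
        gm = cross.to_genotype_matrix().subset_markers(np.arange(200))
        rng = np.random.default_rng(7)
        y = rng.normal(size=117)
        with pytest.warns(UserWarning):
            pheno_null = permutation_threshold(gm, y, n_perm=300, seed=5)
        geno_max = np.empty(300)
        for k in range(300):
            perm = rng.permutation(117)
            gm_p = GenotypeMatrix(calls=gm.calls[perm], segregants=gm.segregants,
                                  markers=gm.markers)
            geno_max[k] = wilcoxon_scan(gm_p, y).max_lk
        assert ks_2samp(pheno_null.max_lk, geno_max).pvalue > 0.001


def _profile(rows, trait="t2"):
    tab = pd.DataFrame(rows, columns=["chrom", "pos", "lk"])
    tab["n_p1"] = tab["n_p2"] = 50
    tab["mean_p1"] = 6.0
    tab["mean_p2"] = 7.0
    tab["defined"] = True
    tab["marker"] = tab["chrom"] + ":" + tab["pos"].astype(str)
    return LinkageProfile(trait=trait, table=tab)


def _null(threshold=3.0):
    return PermutationNull(trait="t2", n_perm=100, alpha=0.05,
                           max_lk=np.full(100, threshold), seed=0)


class TestCallQtl:
    def test_single_peak_interval_contains_peak(self):
        prof = _profile([("chr1", p, lk) for p, lk in
                         [(10_000, 0.5), (25_000, 3.7), (40_000, 4.5),
                          (55_000, 3.8), (70_000, 1.0)]])
        calls = call_qtl(prof, _null(3.0), drop=1.0)
        assert len(calls) == 1
        q = calls[0]
        assert q.peak_pos == 40_000
        assert q.start <= q.peak_pos <= q.end
        assert (q.start, q.end) == (25_000, 55_000)
        # t2 is a lower-is-better trait and P1 has the lower mean here
        assert q.beneficial_parent == "P1"

    def test_no_marker_above_threshold_gives_empty_list(self):
        prof = _profile([("chr1", 10_000, 1.0), ("chr1", 25_000, 2.0)])
        assert call_qtl(prof, _null(3.0)) == []

    def test_peaks_on_two_chromosomes_give_two_calls(self):
        prof = _profile([("chr1", 10_000, 4.0), ("chr1", 25_000, 1.0),
                         ("chr2", 10_000, 0.5), ("chr2", 30_000, 5.0)])
        calls = call_qtl(prof, _null(3.0))
        assert [q.chrom for q in calls] == ["chr1", "chr2"]

    def test_overlapping_intervals_merge_to_higher_peak(self):
        prof = _profile([("chr1", p, lk) for p, lk in
                         [(10_000, 4.0), (20_000, 3.6), (30_000, 4.4),
                          (40_000, 1.0)]])
        calls = call_qtl(prof, _null(3.0), drop=1.0)
        assert len(calls) == 1
        assert calls[0].peak_pos == 30_000


class TestCandidateGenes:
    def _qtl(self):
        return QtlCall(trait="t2", chrom="chrVII", peak_pos=560_000,
                       peak_marker="chrVII:560000", peak_lk=4.5,
                       start=544_000, end=594_000, threshold=3.0,
                       beneficial_parent="P2", mean_p1=7.0, mean_p2=6.0)

    def test_overlap_and_flag_required(self):
        ann = pd.DataFrame({"gene_id": ["PMA1", "GSC2", "FAR"],
                            "chrom": ["chrVII"] * 3,
                            "start": [560_000, 570_000, 700_000],
                            "end": [562_000, 572_000, 702_000]})
        flags = pd.DataFrame({"gene_id": ["PMA1", "GSC2", "FAR"],
                              "has_ns_snp": [True, False, True]})
        assert candidate_genes(self._qtl(), ann, flags) == ["PMA1"]

    def test_empty_annotation(self):
        ann = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        flags = pd.DataFrame(columns=["gene_id", "has_ns_snp"])
        assert candidate_genes(self._qtl(), ann, flags) == []

    def test_sorted_by_position(self):
        ann = pd.DataFrame({"gene_id": ["B", "A"], "chrom": ["chrVII"] * 2,
                            "start": [580_000, 550_000], "end": [582_000, 552_000]})
        flags = pd.DataFrame({"gene_id": ["A", "B"], "has_ns_snp": [True, True]})
        assert candidate_genes(self._qtl(), ann, flags) == ["A", "B"]


def test_planted_qtl_scan_end_to_end(study_cross):
    """The strong planted locus (49% of t5) is found at genome-wide
    significance within 30 kb of the truth."""
    from fermqtl.synthetic_data import default_architecture

    _, cross = study_cross
    gm = cross.to_genotype_matrix()
    traits = simulate_traits(cross, default_architecture(), seed=11)
    y = traits["t5"].to_numpy()
    prof = wilcoxon_scan(gm, y, trait_name="t5")
    with pytest.warns(UserWarning):
        null = permutation_threshold(gm, y, n_perm=200, seed=11, trait_name="t5")
    calls = call_qtl(prof, null)
    hit = [q for q in calls if q.chrom == "chrXVI" and abs(q.peak_pos - 635_000) <= 30_000]
    assert hit and hit[0].beneficial_parent == "P1"
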