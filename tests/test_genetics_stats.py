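"""Cross-level statistics: heterosis, heritability, transgression, ANOVA,
Duncan letters, allele x pH interaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fermqtl.genetics_stats import (anova_decomposition, duncan_groups,
                                    genetics_report, gxe_analysis, heritability,
                                    heterosis_dm, significance_stars, transgression)


class TestHeterosis:
    def test_published_cross_values(self):
        """Diploid parent / hybrid means reproduce the reported d/m row."""
        assert heterosis_dm(1.30, 0.53, 0.73) == pytest.approx(1.0635, abs=5e-4)
        assert heterosis_dm(5.37, 5.33, 5.53) == pytest.approx(-0.0110, abs=5e-4)
        assert heterosis_dm(3.00, 4.00, 4.00) == pytest.approx(-0.25, abs=1e-12)
        assert heterosis_dm(5.00, 8.60, 7.10) == pytest.approx(-0.3631, abs=5e-4)
        assert heterosis_dm(13.0, 26.0, 15.0) == pytest.approx(-0.36585, abs=5e-5)

    def test_no_divergence_gives_zero(self):
        for x in (0.5, 3.0, -2.0):
            assert heterosis_dm(x, x, x) == 0.0

    def test_zero_mid_parent_rejected(self):
        with pytest.raises(ValueError):
            heterosis_dm(1.0, -2.0, 2.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(h=st.floats(-10, 10), p1=st.floats(0.1, 10), p2=st.floats(0.1, 10),
           c=st.floats(0.1, 50))
    def test_scale_invariance(self, h, p1, p2, c):
        assert heterosis_dm(c * h, c * p1, c * p2) == pytest.approx(
            heterosis_dm(h, p1, p2), rel=1e-9, abs=1e-9)


class TestHeritability:
    def test_definition_and_limits(self):
        assert heritability(1.0, 0.1) == pytest.approx(0.90)
        assert heritability(1.0, 0.0) == 1.0

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert heritability(0.5, 0.6) == 0.0

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.1)
        with pytest.raises(ValueError):
            heritability(1.0, -0.1)

    def test_unbiased_on_synthetic_cross(self):
        """H^2 estimates track Vg/(Vg+Ve) within 0.03 at n=117 over seeds."""
        vg, ve, n, reps = 1.0, 0.25, 117, 200
        truth = vg / (vg + ve)
        est = np.empty(reps)
        for s in range(reps):
            rng = np.random.default_rng(s)
            gvals = rng.normal(0, np.sqrt(vg), n)
            seg_means = gvals + rng.normal(0, np.sqrt(ve / 2), n)  # mean of 2 reps
            est[s] = heritability(np.var(seg_means, ddof=1), ve / 2)
        # the estimator targets Vg/(Vg + Ve/2) with replicate means
        expected = vg / (vg + ve / 2)
        assert abs(est.mean() - expected) <= 0.03


class TestTransgression:
    def test_rule_application(self):
        pct, count = transgression([12.5, 11.0, 7.0], 5.0, 10.0, env_sd=1.0, k=2.0)
        assert count == 1 and pct == pytest.approx(100 / 3)

    def test_all_inside_parental_range(self):
        pct, count = transgression([6, 7, 8], 5.0, 10.0, env_sd=0.5)
        assert (pct, count) == (0.0, 0)

    def test_boundary_is_strict(self):
        pct, count = transgression([10.0], 5.0, 10.0, env_sd=1.0, k=0.0)
        assert count == 0


class TestAnovaDecomposition:
    def test_deterministic_indicator_trait(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, size=(240, 3))
        dec = anova_decomposition(g[:, 0].astype(float), g)
        assert dec.share("QTL1") == pytest.approx(100.0, abs=1e-9)
        for term in ("QTL2", "QTL3", "residual"):
            assert dec.share(term) == pytest.approx(0.0, abs=1e-9)

    def test_pure_noise_shares_small_and_bounded(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, size=(117, 3))
        dec = anova_decomposition(rng.normal(size=117), g)
        non_res = dec.explained_pct
        assert 0 <= non_res <= 100
        assert non_res < 20

    def test_planted_share_recovered(self):
        rng = np.random.default_rng(2)
        n = 5000
        g = rng.integers(0, 2, size=(n, 3))
        beta = 2 * np.sqrt(0.3 / 0.7)
        y = beta * g[:, 1] + rng.normal(size=n)
        dec = anova_decomposition(y, g)
        assert dec.share("QTL2") == pytest.approx(30.0, abs=2.0)

    def test_relabeling_consistency(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(117, 3))
        y = g[:, 0] * 0.8 + rng.normal(size=117)
        a = anova_decomposition(y, g)
        perm = rng.permutation(117)
        b = anova_decomposition(y[perm], g[perm])
        assert np.allclose(a.table["share_pct"], b.table["share_pct"])

    def test_missing_genotypes_excluded_and_empty_cells_dropped(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 2, size=(120, 3)).astype(float)
        g[:3, 0] = np.nan
        g[(g[:, 1] == 1) & (g[:, 2] == 1), 2] = 0  # empty (1,1) cell for QTL2:QTL3
        with pytest.warns(UserWarning, match="dropped"):
            dec = anova_decomposition(rng.normal(size=120), g)
        assert dec.n_used == 117
        assert "QTL2:QTL3" in dec.dropped_terms
        assert "QTL2:QTL3" not in set(dec.table["term"])


class TestDuncan:
    def test_widely_separated_means(self):
        assert duncan_groups([0.0, 50.0], [10, 10], mse=1.0, df=18) == ["a", "b"]

    def test_equal_means_share_a_letter(self):
        assert duncan_groups([1.0, 1.0, 1.0], [5, 5, 5], mse=0.5, df=12) == \
            ["a", "a", "a"]

    def test_three_group_oracle(self):
        """Means {0, 0.1, 3.0}, SD 0.2, n = 10: the two low means are not
        separable (diff 0.1 < R_2 ~ 0.18) but 3.0 is."""
        from scipy.stats import studentized_range

        se = np.sqrt(0.04 / 10)
        r2 = studentized_range.ppf(0.95, 2, 27) * se
        assert 0.1 < r2 < 3.0  # oracle: explicit critical-range computation
        letters = duncan_groups([0.0, 0.1, 3.0], [10, 10, 10], mse=0.04, df=27)
        assert letters == ["a", "a", "b"]

    def test_two_groups_match_pooled_t_decision(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(0, 1, 12)
            b = rng.normal(rng.uniform(0, 1.5), 1, 12)
            mse = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
            letters = duncan_groups([a.mean(), b.mean()], [12, 12], mse, 22)
            t_p = stats.ttest_ind(a, b).pvalue
            assert (letters[0] != letters[1]) == (t_p <= 0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            duncan_groups([1.0], [5], 1.0, 10)
        with pytest.raises(ValueError):
            duncan_groups([1.0, 2.0], [5, 5], 1.0, 0)


def _gxe_from_summary(cells, n=3):
    """Build replicate data hitting given (allele, env) -> (mean, se) exactly."""
    rows = []
    for (allele, env), (mean, se) in cells.items():
        d = se * np.sqrt(n)
        for v in (mean - d, mean, mean + d):
            rows.append((v, allele, env))
    return pd.DataFrame(rows, columns=["value", "allele", "env"])


class TestGxe:
    def test_published_low_ph_t2_contrast_is_highly_significant(self):
        """Reconstructed hemizygote t2 at pH 2.8 (7.46 +- 0.07 vs 5.6 +- 0.06,
        n=3): the pooled-variance test lands in the *** tier."""
        df = _gxe_from_summary({("GN", 2.8): (7.46, 0.07), ("SB", 2.8): (5.6, 0.06),
                                ("GN", 3.3): (5.1, 0.20), ("SB", 3.3): (4.6, 0.01)})
        res = gxe_analysis(df)
        row = res.per_env[res.per_env["env"] == 2.8].iloc[0]
        assert row["stars"] == "***"
        assert row["diff"] == pytest.approx(1.86, abs=1e-9)

    def test_null_interaction_rejection_rate(self):
        """Same allele effect in every environment: the interaction test
        rejects at ~alpha across seeds."""
        reject = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(s)
            rows = []
            for env in (2.8, 3.0, 3.3):
                for allele, shift in (("A", 0.0), ("B", 1.0)):
                    for v in rng.normal(shift, 0.3, size=4):
                        rows.append((v, allele, env))
            res = gxe_analysis(pd.DataFrame(rows, columns=["value", "allele", "env"]))
            reject += res.interaction_p <= 0.05
        assert abs(reject / reps - 0.05) <= 0.05

    def test_sign_flip_power(self):
        """+1 at pH 2.8 and -1 at pH 3.3 (SD 0.2, 30/cell) is detected at
        p < 0.001 in essentially every seeded replicate."""
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            rows = []
            for env, eff in ((2.8, 1.0), (3.3, -1.0)):
                for allele, sign in (("A", 0.5), ("B", -0.5)):
                    for v in rng.normal(eff * sign, 0.2, size=30):
                        rows.append((v, allele, env))
            res = gxe_analysis(pd.DataFrame(rows, columns=["value", "allele", "env"]))
            hits += res.interaction_p < 0.001
        assert hits >= 39

    def test_empty_cell_rejected(self):
        df = _gxe_from_summary({("GN", 2.8): (7.0, 0.1), ("SB", 2.8): (5.0, 0.1),
                                ("GN", 3.3): (5.0, 0.1)})
        with pytest.raises(ValueError, match="cell"):
            gxe_analysis(df)


def test_significance_star_tiers():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.2, np.nan)] == \
        ["***", "**", "*", "", ""]


def test_genetics_report_table():
    rng = np.random.default_rng(6)
    seg = pd.DataFrame({"rate": rng.normal(1.0, 0.2, 117)})
    parents = pd.DataFrame({"rate": [0.8, 1.2]}, index=["P1", "P2"])
    rep = genetics_report(seg, parents, {"rate": 1.3}, {"rate": 0.05})
    row = rep.iloc[0]
    assert row["d_m"] == pytest.approx(0.3, abs=1e-9)
    assert 0 <= row["heritability_pct"] <= 100
    assert 0 <= row["transgression_pct"] <= 100
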