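"""Cross-level genetics statistics.

Covers the summary statistics of an F1-hybrid QTL design: heterosis of the
hybrid against the mid-parent value (d/m), broad-sense heritability from the
segregant vs. replicate variance, transgressive segregation beyond the
parental range, an ANOVA decomposition of trait variance over the mapped QTL
and their pairwise interactions, Duncan's multiple-range letters for
haplotype-class means, and the allele x environment (base-wine pH) analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

__all__ = [
    "heterosis_dm", "heritability", "transgression",
    "anova_decomposition", "VarianceDecomposition",
    "duncan_groups", "gxe_analysis", "GxeResult",
    "significance_stars", "genetics_report",
]


def heterosis_dm(hybrid: float, p1: float, p2: float) -> float:
    """Heterosis index d/m = (hybrid - mid-parent) / mid-parent.

    The mid-parent value is m = (p1 + p2) / 2; a positive d/m means the
    hybrid exceeds the parental average on the trait's own scale (the index
    is invariant to rescaling all three inputs).
    """
    m = (p1 + p2) / 2.0
    if m == 0:
        raise ValueError("mid-parent value is zero; d/m is undefined")
    return (hybrid - m) / m


def heritability(seg_var: float, env_var: float) -> float:
    """Broad-sense heritability H^2 = (V_segregants - V_env) / V_segregants.

    ``seg_var`` is the trait variance among segregant means, ``env_var`` the
    replicate/environmental variance; the estimate is clamped to [0, 1]
    (with a warning when the environmental variance exceeds the segregant
    variance, which can happen by sampling noise for low-heritability
    traits).
    """
    if seg_var <= 0:
        raise ValueError("segregant variance must be positive")
    if env_var < 0:
        raise ValueError("environmental variance must be >= 0")
    h2 = (seg_var - env_var) / seg_var
    if h2 < 0:
        warnings.warn("environmental variance exceeds segregant variance; "
                      "H^2 clamped to 0", stacklevel=2)
        return 0.0
    return min(h2, 1.0)


def transgression(seg_values, p1_mean: float, p2_mean: float, env_sd: float,
                  k: float = 2.0) -> tuple[float, int]:
    """Percentage and count of transgressive segregants.

    A segregant is transgressive when its trait value falls strictly outside
    the parental range widened by ``k`` environmental SDs on each side.
    Returns (percentage over all segregants, count).
    """
    if env_sd < 0:
        raise ValueError("env_sd must be >= 0")
    vals = np.asarray(seg_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    lo = min(p1_mean, p2_mean) - k * env_sd
    hi = max(p1_mean, p2_mean) + k * env_sd
    count = int(((vals < lo) | (vals > hi)).sum())
    pct = 100.0 * count / len(vals) if len(vals) else 0.0
    return pct, count


@dataclass
class VarianceDecomposition:
    """Sequential ANOVA shares of trait variance over mapped QTL.

    ``table`` has one row per model term (mains first, then pairwise
    interactions, then residual) with sum of squares, share of the total SS
    in percent, F and p; diagnostics carry the Levene (median-centred)
    homoscedasticity and Shapiro-Wilk residual-normality p-values.
    """

    trait: str
    table: pd.DataFrame
    n_used: int
    dropped_terms: list[str] = field(default_factory=list)
    levene_p: float = float("nan")
    shapiro_p: float = float("nan")

    def share(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term, "share_pct"]
        return float(row.iloc[0]) if len(row) else float("nan")

    @property
    def explained_pct(self) -> float:
        non_res = self.table["term"] != "residual"
        return float(self.table.loc[non_res, "share_pct"].sum())


def anova_decomposition(trait_values, genotypes, term_names=None,
                        trait_name: str = "trait") -> VarianceDecomposition:
    """Variance decomposition Y = m + sum(QTLk) + sum(QTLj*QTLk) + E.

    ``genotypes`` is an (n, k) array / DataFrame of genotype classes at the
    peak markers (k = 2 or 3; missing as NaN or the MISSING code -1).
    Segregants missing any genotype or the trait are excluded. Sums of
    squares are sequential (terms entered mains-first, in the given order)
    and each share is the term's SS over the total SS x 100. Pairwise
    interactions whose design cells are empty are dropped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    g = pd.DataFrame(genotypes).copy()
    if term_names is None:
        term_names = [f"QTL{i + 1}" for i in range(g.shape[1])]
    g.columns = list(term_names)
    if g.shape[1] < 2:
        raise ValueError("at least two QTL terms are required")
    y = np.asarray(trait_values, dtype=float)
    if len(y) != len(g):
        raise ValueError("trait and genotype lengths differ")
    g = g.replace(-1, np.nan)
    keep = np.isfinite(y) & g.notna().all(axis=1).to_numpy()
    df = g.loc[keep].astype("Int64").astype(str).reset_index(drop=True)
    df["y"] = y[keep]

    for t in term_names:
        if df[t].nunique() < 2:
            raise ValueError(f"term {t} has fewer than 2 genotype classes")

    pairs = [(i, j) for i in range(len(term_names)) for j in range(i + 1, len(term_names))]
    dropped = []
    inter_terms = []
    for i, j in pairs:
        a, b = term_names[i], term_names[j]
        cells = pd.crosstab(df[a], df[b])
        if (cells.to_numpy() == 0).any():
            dropped.append(f"{a}:{b}")
            warnings.warn(f"interaction {a}:{b} dropped: empty genotype "
                          "combination", stacklevel=2)
        else:
            inter_terms.append(f"C({a}):C({b})")
    formula = "y ~ " + " + ".join([f"C({t})" for t in term_names] + inter_terms)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)

    ss_total = float(anova["sum_sq"].sum())
    rows = []
    for name, row in anova.iterrows():
        term = (name.replace("C(", "").replace(")", "")
                if name != "Residual" else "residual")
        rows.append({"term": term, "df": float(row["df"]), "ss": float(row["sum_sq"]),
                     "share_pct": 100.0 * float(row["sum_sq"]) / ss_total,
                     "F": float(row.get("F", np.nan)),
                     "p": float(row.get("PR(>F)", np.nan))})
    table = pd.DataFrame(rows)

    groups = [grp["y"].to_numpy() for _, grp in df.groupby(term_names, sort=True)
              if len(grp) > 1]
    levene_p = float(stats.levene(*groups, center="median").pvalue) if len(groups) > 1 else np.nan
    resid = fit.resid.to_numpy()
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
    return VarianceDecomposition(trait=trait_name, table=table, n_used=int(keep.sum()),
                                 dropped_terms=dropped, levene_p=levene_p,
                                 shapiro_p=shapiro_p)


def duncan_groups(means, sizes, mse: float, df: float, alpha: float = 0.05) -> list[str]:
    """Duncan's multiple-range letters for a set of group means.

    Sorted means are compared with critical ranges
    ``R_p = q(1 - (1-alpha)^(p-1); p, df) * sqrt(MSE / n_h)`` (studentized
    range at Duncan's protection level for a span of p means, harmonic-mean
    group size for unequal n). Ranges contained in a non-significant wider
    range are declared non-significant as well; groups sharing a letter do
    not differ at level alpha. With two groups the procedure reduces to the
    pooled t-test decision.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(means) < 2 or len(means) != len(sizes):
        raise ValueError("need >= 2 groups with matching sizes")
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    k = len(means)
    n_h = len(sizes) / np.sum(1.0 / sizes)
    se = np.sqrt(mse / n_h)
    order = np.argsort(-means)  # descending
    sorted_means = means[order]

    crit = {p: studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df) * se
            for p in range(2, k + 1)}
    ns = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(ns, True)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if sorted_means[i] - sorted_means[j] <= crit[span]:
                ns[i, j] = True
    # containment: a sub-range of a non-significant range is non-significant
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if ns[i, j]:
                ns[i + 1, j] = True
                ns[i, j - 1] = True
    # maximal non-significant intervals over the sorted order
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    member: list[list[int]] = [[] for _ in range(k)]  # intervals per sorted index
    for idx, (lo, hi) in enumerate(maximal):
        for s in range(lo, hi + 1):
            member[s].append(idx)
    # letters named in input order of first appearance
    letter_of: dict[int, str] = {}
    letters_out = []
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    for g in range(k):
        labs = []
        for iv in member[rank_of[g]]:
            if iv not in letter_of:
                letter_of[iv] = chr(ord("a") + len(letter_of))
            labs.append(letter_of[iv])
        letters_out.append("".join(sorted(labs)))
    return letters_out


def significance_stars(p: float) -> str:
    """Tiered significance marks: *** p<=0.001, ** p<=0.01, * p<=0.05."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class GxeResult:
    """Allele effects per environment plus the interaction test."""

    trait: str
    per_env: pd.DataFrame
    interaction_F: float
    interaction_p: float
    allele_p: float
    env_p: float


def gxe_analysis(data: pd.DataFrame, value_col: str = "value",
                 allele_col: str = "allele", env_col: str = "env",
                 trait_name: str | None = None) -> GxeResult:
    """Two-allele x environment analysis of one trait.

    Per environment the two allele groups are compared with a two-sided
    pooled-variance t test (mean difference plus significance stars); a
    two-way ANOVA on the full table supplies the allele x environment
    interaction F test. Every allele x environment cell must hold at least
    two replicates.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value_col, allele_col, env_col]].dropna().copy()
    df.columns = ["y", "allele", "env"]
    alleles = sorted(df["allele"].unique())
    envs = sorted(df["env"].unique())
    if len(alleles) != 2:
        raise ValueError("gxe_analysis expects exactly two alleles")
    if len(envs) < 2:
        raise ValueError("at least two environments are required")
    cells = df.groupby(["allele", "env"]).size()
    if len(cells) < len(alleles) * len(envs) or (cells < 2).any():
        raise ValueError("every allele x environment cell needs >= 2 replicates")

    rows = []
    for env in envs:
        sub = df[df["env"] == env]
        g1 = sub.loc[sub["allele"] == alleles[0], "y"].to_numpy()
        g2 = sub.loc[sub["allele"] == alleles[1], "y"].to_numpy()
        t, p = stats.ttest_ind(g1, g2, equal_var=True)
        rows.append({"env": env,
                     f"mean_{alleles[0]}": g1.mean(), f"mean_{alleles[1]}": g2.mean(),
                     "diff": g1.mean() - g2.mean(), "t": float(t), "p": float(p),
                     "stars": significance_stars(float(p))})
    per_env = pd.DataFrame(rows)

    fit = smf.ols("y ~ C(allele) * C(env)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    inter = anova.loc["C(allele):C(env)"]
    return GxeResult(trait=trait_name or value_col, per_env=per_env,
                     interaction_F=float(inter["F"]), interaction_p=float(inter["PR(>F)"]),
                     allele_p=float(anova.loc["C(allele)", "PR(>F)"]),
                     env_p=float(anova.loc["C(env)", "PR(>F)"]))


def genetics_report(seg_traits: pd.DataFrame, parent_means: pd.DataFrame,
                    hybrid_means: pd.Series | dict, env_sd: dict[str, float],
                    trait_names=None, k: float = 2.0) -> pd.DataFrame:
    """Per-trait cross summary: d/m, H^2, transgression.

    ``seg_traits`` holds one row per segregant with trait columns;
    ``parent_means`` two rows (index P1, P2) of parental trait means;
    ``hybrid_means`` the hybrid's; ``env_sd`` the replicate/environmental SD
    per trait (its square is the environmental variance in H^2).
    """
    if trait_names is None:
        trait_names = [c for c in seg_traits.columns if c in parent_means.columns]
    hybrid_means = pd.Series(hybrid_means)
    rows = []
    for t in trait_names:
        vals = seg_traits[t].dropna().to_numpy()
        p1m, p2m = float(parent_means.loc["P1", t]), float(parent_means.loc["P2", t])
        hyb = float(hybrid_means[t])
        sd = float(env_sd.get(t, np.nan)) if isinstance(env_sd, dict) else float(env_sd[t])
        seg_var = float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan
        row = {"trait": t, "p1_mean": p1m, "p2_mean": p2m, "hybrid_mean": hyb,
               "mid_parent": (p1m + p2m) / 2.0, "n_segregants": len(vals)}
        try:
            row["d_m"] = heterosis_dm(hyb, p1m, p2m)
        except ValueError:
            row["d_m"] = np.nan
        if np.isfinite(seg_var) and seg_var > 0 and np.isfinite(sd):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["heritability_pct"] = 100.0 * heritability(seg_var, sd ** 2)
        else:
            row["heritability_pct"] = np.nan
        if np.isfinite(sd):
            pct, count = transgression(vals, p1m, p2m, sd, k=k)
            row["transgression_pct"], row["transgression_n"] = pct, count
        else:
            row["transgression_pct"] = row["transgression_n"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
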