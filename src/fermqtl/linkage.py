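"""Genome scan by Wilcoxon rank-sum, permutation thresholds, QTL calls.

At every passing marker the segregants are split by inherited parental allele
and the trait is compared between the two groups with a two-sided
Mann-Whitney / Wilcoxon rank-sum test; the linkage score is
LK = -log10(p). Genome-wide significance is calibrated empirically: the trait
vector is permuted across segregants (genotypes fixed), the scan repeated, the
maximum LK recorded per permutation, and the (1 - alpha) quantile of those
maxima becomes the threshold. Peaks above the threshold are reported with a
1-LK-unit support interval and the beneficial parent at the peak.

Numerics. Exact p-values are used when both groups have <= 25 members and the
trait is tie-free in the marker's subset; otherwise a normal approximation
with tie and continuity corrections, refined with a guarded fourth-moment
(Edgeworth) term that keeps small-group tail p-values within ~0.15 log10 units
of the exact ones. The permutation engine evaluates the null with the same
approximate statistic, vectorized over markers and permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import mannwhitneyu, rankdata

from ._rng import substream
from .genotyping import MISSING, P1, P2, GenotypeMatrix
from .kinetics import TRAIT_DIRECTIONS

__all__ = [
    "LinkageProfile", "PermutationNull", "QtlCall",
    "wilcoxon_scan", "permutation_threshold", "call_qtl", "candidate_genes",
]

_MIN_P = 1e-300


@dataclass
class LinkageProfile:
    """Per-marker linkage scores for one trait.

    ``table`` has one row per scanned marker: chrom, pos, marker, n_p1, n_p2,
    mean_p1, mean_p2, lk (NaN where undefined) and ``defined``.
    """

    trait: str
    table: pd.DataFrame
    min_group: int = 10
    method: str = "auto"

    @property
    def max_lk(self) -> float:
        vals = self.table.loc[self.table["defined"], "lk"]
        return float(vals.max()) if len(vals) else float("nan")


@dataclass
class PermutationNull:
    """Genome-wide null distribution of the maximum LK score."""

    trait: str
    n_perm: int
    alpha: float
    max_lk: np.ndarray
    seed: int

    def threshold(self, alpha: float | None = None) -> float:
        """Empirical (1 - alpha) quantile of the permuted maxima (type-7)."""
        a = self.alpha if alpha is None else alpha
        return float(np.quantile(self.max_lk, 1.0 - a))


@dataclass
class QtlCall:
    """A significant linkage peak with its support interval."""

    trait: str
    chrom: str
    peak_pos: int
    peak_marker: str
    peak_lk: float
    start: int
    end: int
    threshold: float
    beneficial_parent: str | None
    mean_p1: float
    mean_p2: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "trait", "chrom", "peak_pos", "peak_marker", "peak_lk",
            "start", "end", "threshold", "beneficial_parent", "mean_p1", "mean_p2")}


# ---------------------------------------------------------------------------
# p-value machinery

def _tie_sum(x: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def _approx_two_sided_p(u, m, n, tie_sum=0.0):
    """Two-sided rank-sum p from the refined normal approximation.

    Continuity-corrected z plus a guarded Edgeworth kurtosis term
    (the exact U null is symmetric and platykurtic,
    gamma2 = -6/5 * (m^2 + n^2 + mn + m + n) / (mn(m+n+1))); the correction
    is floored at 5% of the plain normal tail so it can never drive the
    p-value negative or non-monotone in the far tail.
    """
    u = np.asarray(u, dtype=float)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    nn = m + n
    mean = m * n / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tie_corr = np.where(nn > 1, np.asarray(tie_sum, dtype=float) / (nn * (nn - 1.0)), 0.0)
        var = m * n / 12.0 * ((nn + 1.0) - tie_corr)
        sd = np.sqrt(var)
        z = np.maximum(np.abs(u - mean) - 0.5, 0.0) / np.where(sd > 0, sd, np.inf)
        gamma2 = -1.2 * (m * m + n * n + m * n + m + n) / (m * n * (nn + 1.0))
    s0 = ndtr(-z)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    s_edge = s0 + phi * (gamma2 / 24.0) * (z ** 3 - 3.0 * z)
    s = np.maximum(s_edge, 0.05 * s0)
    return np.clip(2.0 * s, _MIN_P, 1.0)


def _exact_two_sided_p(x_p1: np.ndarray, x_p2: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(x_p2, x_p1, alternative="two-sided", method="exact")
    return float(res.pvalue)


def _u_stat(x_p1: np.ndarray, x_p2: np.ndarray) -> float:
    """Mann-Whitney U of the P2 group (pairwise definition, ties count 1/2)."""
    gt = (x_p2[:, None] > x_p1[None, :]).sum()
    eq = (x_p2[:, None] == x_p1[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


# ---------------------------------------------------------------------------
# observed scan

def wilcoxon_scan(gm: GenotypeMatrix, trait, trait_name: str | None = None,
                  min_group: int = 10, method: str = "auto") -> LinkageProfile:
    """Two-sided rank-sum genome scan of one trait over the passing markers.

    Parameters
    ----------
    gm : GenotypeMatrix
        Calls plus marker metadata; only markers with filter status "pass"
        (or all markers when the map has not been filtered) are scanned.
    trait : Series or array
        Trait value per segregant (Series indexed by segregant id, or an
        array aligned with ``gm.segregants``). NaN values drop the segregant.
    min_group : int
        Markers where either allele group (after removing missing genotypes
        and undefined traits) has fewer members get an undefined LK rather
        than zero, so they cannot deflate permutation thresholds.
    method : {"auto", "exact", "approx"}
        "auto" uses the exact null when both groups have <= 25 members and
        the subset is tie-free, the refined normal approximation otherwise.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    x = _align_trait(gm, trait)
    if trait_name is None:
        trait_name = getattr(trait, "name", None) or "trait"

    ok_rows = np.isfinite(x)
    if ok_rows.sum() < 2 * min_group:
        raise ValueError("trait defined for fewer than 2*min_group segregants")
    if np.unique(x[ok_rows]).size <= 1:
        warnings.warn("constant trait: all LK scores are 0", stacklevel=2)

    pass_mask = gm.pass_mask()
    calls = gm.calls[:, pass_mask]
    meta = gm.markers.loc[pass_mask].reset_index(drop=True)

    rows = []
    for j in range(calls.shape[1]):
        a = ok_rows & (calls[:, j] == P1)
        b = ok_rows & (calls[:, j] == P2)
        m, n = int(a.sum()), int(b.sum())
        rec = {"chrom": meta["chrom"].iat[j], "pos": int(meta["pos"].iat[j]),
               "n_p1": m, "n_p2": n,
               "mean_p1": float(x[a].mean()) if m else np.nan,
               "mean_p2": float(x[b].mean()) if n else np.nan}
        if m < min_group or n < min_group:
            rec.update(lk=np.nan, p=np.nan, defined=False)
        else:
            xa, xb = x[a], x[b]
            subset = np.concatenate([xa, xb])
            tie_sum = _tie_sum(subset)
            use_exact = (method == "exact" or
                         (method == "auto" and m <= 25 and n <= 25 and tie_sum == 0))
            if use_exact:
                p = _exact_two_sided_p(xa, xb)
            else:
                p = float(_approx_two_sided_p(_u_stat(xa, xb), m, n, tie_sum))
            rec.update(lk=-np.log10(max(p, _MIN_P)), p=p, defined=True)
        rows.append(rec)
    table = pd.DataFrame(rows)
    table["marker"] = table["chrom"].astype(str) + ":" + table["pos"].astype(str)
    return LinkageProfile(trait=trait_name, table=table, min_group=min_group, method=method)


def _align_trait(gm: GenotypeMatrix, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        if not trait.index.is_unique:
            raise ValueError("trait index has duplicate segregants")
        return trait.reindex(gm.segregants).to_numpy(dtype=float)
    x = np.asarray(trait, dtype=float)
    if x.shape != (gm.n_segregants,):
        raise ValueError("trait length does not match segregants")
    return x


# ---------------------------------------------------------------------------
# permutation null

class _ApproxScanEngine:
    """Vectorized approximate scan used for permutation nulls.

    Precomputes, per passing marker, the allele-group masks and null moments;
    each permutation then costs one small matrix product. Requires a tie-free
    trait when genotypes have missing cells (subset tie structure would
    otherwise change per permutation); with ties and no missing cells the
    global tie correction is exact.
    """

    def __init__(self, gm: GenotypeMatrix, x: np.ndarray, min_group: int):
        ok = np.isfinite(x)
        calls = gm.calls[:, gm.pass_mask()][ok]
        self.x = x[ok]
        self.a = calls == P1
        self.b = calls == P2
        self.m = self.a.sum(axis=0).astype(float)
        self.n = self.b.sum(axis=0).astype(float)
        self.defined = (self.m >= min_group) & (self.n >= min_group)
        self.has_missing = bool((calls == MISSING).any())
        self.tie_sum = _tie_sum(self.x)
        if self.has_missing and self.tie_sum > 0:
            raise _NeedsSlowPath
        if self.has_missing:
            xx = self.x
            self.c_mat = (xx[:, None] > xx[None, :]).astype(np.float64)
            self.a_f = self.a.astype(np.float64)
        else:
            self.ranks = rankdata(self.x)
            self.b_f = self.b.astype(np.float64)
            self.offset = self.n * (self.n + 1.0) / 2.0

    def lk(self, perm: np.ndarray) -> np.ndarray:
        """LK scores at the defined markers for one trait permutation."""
        if self.has_missing:
            c = self.c_mat[perm][:, perm]
            u = ((c @ self.a_f) * self.b).sum(axis=0)
        else:
            u = self.ranks[perm] @ self.b_f - self.offset
        p = _approx_two_sided_p(u[self.defined], self.m[self.defined],
                                self.n[self.defined], self.tie_sum)
        return -np.log10(p)


class _NeedsSlowPath(Exception):
    pass


def permutation_threshold(gm: GenotypeMatrix, trait, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          trait_name: str | None = None,
                          min_group: int = 10) -> PermutationNull:
    """Genome-wide significance threshold from trait permutations.

    The trait vector is shuffled uniformly across segregants (genotypes
    untouched), the full scan is recomputed, and the maximum LK over the
    defined markers recorded; the threshold is the empirical (1 - alpha)
    quantile (linear / type-7 interpolation) of those maxima. One seeded
    stream per trait keeps thresholds reproducible trait by trait.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm * alpha < 20:
        warnings.warn("n_perm is small for this alpha; the threshold quantile "
                      "will be noisy", stacklevel=2)
    x = _align_trait(gm, trait)
    if trait_name is None:
        trait_name = getattr(trait, "name", None) or "trait"
    rng = substream(seed, f"perm:{trait_name}")
    n_eff = int(np.isfinite(x).sum())

    try:
        engine = _ApproxScanEngine(gm, x, min_group)
        if not engine.defined.any():
            raise ValueError("no marker meets the min_group requirement")
        max_lk = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(n_eff)
            max_lk[k] = engine.lk(perm).max()
    except _NeedsSlowPath:
        # tied trait with missing genotypes: per-permutation subset ties
        ok = np.isfinite(x)
        idx = np.nonzero(ok)[0]
        max_lk = np.empty(n_perm)
        xp = x.copy()
        for k in range(n_perm):
            xp[idx] = x[idx][rng.permutation(n_eff)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = wilcoxon_scan(gm, xp, trait_name=trait_name,
                                     min_group=min_group, method="approx")
            max_lk[k] = prof.max_lk
    return PermutationNull(trait=trait_name, n_perm=n_perm, alpha=alpha,
                           max_lk=max_lk, seed=seed)


# ---------------------------------------------------------------------------
# QTL calling

def call_qtl(profile: LinkageProfile, null: PermutationNull, drop: float = 1.0,
             trait_direction: int | None = None) -> list[QtlCall]:
    """Call significant peaks with LK-drop support intervals.

    Per chromosome, local maxima above the permutation threshold become
    peaks; the support interval runs from the peak to the outermost flanking
    markers still within ``drop`` LK units of it, and overlapping intervals
    on one chromosome merge into the higher peak. The beneficial parent is
    the allele group with the better mean in the trait's natural direction
    (higher for Pmax/rate, lower for the tX times).
    """
    thr = null.threshold()
    if trait_direction is None:
        trait_direction = TRAIT_DIRECTIONS.get(profile.trait)
    tab = profile.table[profile.table["defined"]].reset_index(drop=True)
    calls: list[QtlCall] = []
    for chrom, sub in tab.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        lk = sub["lk"].to_numpy()
        if not (lk > thr).any():
            continue
        intervals = []
        for i in np.nonzero(lk > thr)[0]:
            left_ok = i == 0 or lk[i] >= lk[i - 1]
            right_ok = i == len(lk) - 1 or lk[i] >= lk[i + 1]
            if not (left_ok and right_ok):
                continue
            lo = i
            while lo > 0 and lk[lo - 1] >= lk[i] - drop:
                lo -= 1
            hi = i
            while hi < len(lk) - 1 and lk[hi + 1] >= lk[i] - drop:
                hi += 1
            intervals.append((lo, hi, i))
        intervals.sort()
        merged: list[list[int]] = []
        for lo, hi, i in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                if lk[i] > lk[merged[-1][2]]:
                    merged[-1][2] = i
            else:
                merged.append([lo, hi, i])
        for lo, hi, i in merged:
            row = sub.iloc[i]
            benef = None
            if trait_direction is not None and np.isfinite(row["mean_p1"]) \
                    and np.isfinite(row["mean_p2"]):
                better_p1 = (row["mean_p1"] - row["mean_p2"]) * trait_direction > 0
                benef = "P1" if better_p1 else "P2"
            calls.append(QtlCall(
                trait=profile.trait, chrom=str(chrom),
                peak_pos=int(row["pos"]), peak_marker=str(row["marker"]),
                peak_lk=float(row["lk"]),
                start=int(sub["pos"].iat[lo]), end=int(sub["pos"].iat[hi]),
                threshold=thr, beneficial_parent=benef,
                mean_p1=float(row["mean_p1"]), mean_p2=float(row["mean_p2"])))
    return calls


def candidate_genes(qtl: QtlCall, annotation: pd.DataFrame,
                    ns_snp_flags: pd.DataFrame) -> list[str]:
    """Genes overlapping the support interval that carry a parental ns-SNP.

    ``annotation`` needs columns gene_id, chrom, start, end (1-based
    inclusive); ``ns_snp_flags`` columns gene_id, has_ns_snp. Returns gene
    ids sorted by start position.
    """
    if len(annotation) == 0:
        return []
    flagged = set(ns_snp_flags.loc[ns_snp_flags["has_ns_snp"].astype(bool), "gene_id"])
    sub = annotation[(annotation["chrom"] == qtl.chrom) &
                     (annotation["end"] >= qtl.start) &
                     (annotation["start"] <= qtl.end)]
    sub = sub[sub["gene_id"].isin(flagged)].sort_values("start")
    return list(sub["gene_id"])
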