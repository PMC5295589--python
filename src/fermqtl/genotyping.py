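"""Segregant genotyping from low-coverage allele counts and marker-map filters.

Two homozygous parents are compared against the same reference genome; the
sites where their calls disagree ("distinguishing SNPs") become markers. Each
haploid segregant of the cross is sequenced at low coverage (a few reads per
site), reads are tallied per parental allele, and a simple count rule assigns
each segregant x marker cell to P1, P2 or missing. The marker map is then
filtered for Mendelian 1:1 segregation (chi-square), for callability, and
thinned to roughly one marker per 15 kb window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "P1", "P2", "MISSING", "CALL_LABELS",
    "AlleleCountTable", "GenotypeMatrix",
    "distinguishing_snps", "call_genotypes", "chi_square_1to1", "build_marker_map",
]

P1: int = 0
P2: int = 1
MISSING: int = -1
CALL_LABELS = {P1: "P1", P2: "P2", MISSING: "NA"}
_LABEL_CODES = {"P1": P1, "P2": P2, "NA": MISSING, "": MISSING}

_ALLELES = frozenset("ACGT")


def _chrom_order(*frames: pd.DataFrame) -> list[str]:
    """Chromosome names in first-appearance order across the given frames."""
    seen: dict[str, None] = {}
    for fr in frames:
        for c in fr["chrom"]:
            seen.setdefault(c, None)
    return list(seen)


def _sort_sites(df: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    key = {c: i for i, c in enumerate(order)}
    return (df.assign(_k=df["chrom"].map(key))
              .sort_values(["_k", "pos"], kind="mergesort")
              .drop(columns="_k").reset_index(drop=True))


@dataclass
class AlleleCountTable:
    """Per segregant x site read counts supporting each parental allele.

    ``n_p1``/``n_p2``/``n_other`` are (n_segregants, n_sites) integer arrays
    aligned with ``variants`` (chrom, pos, ref, p1_allele, p2_allele rows,
    1-based positions).
    """

    variants: pd.DataFrame
    segregants: list[str]
    n_p1: np.ndarray
    n_p2: np.ndarray
    n_other: np.ndarray

    def __post_init__(self):
        shape = (len(self.segregants), len(self.variants))
        for arr_name in ("n_p1", "n_p2", "n_other"):
            arr = getattr(self, arr_name)
            if arr.shape != shape:
                raise ValueError(f"{arr_name} has shape {arr.shape}, expected {shape}")
            if (arr < 0).any():
                raise ValueError("read counts must be non-negative")

    def to_long(self) -> pd.DataFrame:
        n_seg, n_site = self.n_p1.shape
        return pd.DataFrame({
            "segregant": np.repeat(self.segregants, n_site),
            "chrom": np.tile(self.variants["chrom"].to_numpy(), n_seg),
            "pos": np.tile(self.variants["pos"].to_numpy(), n_seg),
            "n_p1": self.n_p1.ravel(),
            "n_p2": self.n_p2.ravel(),
            "n_other": self.n_other.ravel(),
        })

    @classmethod
    def from_long(cls, long_df: pd.DataFrame, variants: pd.DataFrame) -> "AlleleCountTable":
        """Assemble the wide table from long rows at the given marker sites.

        Rows at (chrom, pos) absent from ``variants`` are ignored with a
        warning; sites without a row for a segregant get zero counts.
        """
        site_key = {(c, p): j for j, (c, p) in
                    enumerate(zip(variants["chrom"], variants["pos"]))}
        segs = sorted(long_df["segregant"].unique())
        seg_key = {s: i for i, s in enumerate(segs)}
        n_p1 = np.zeros((len(segs), len(variants)), dtype=np.int64)
        n_p2 = np.zeros_like(n_p1)
        n_other = np.zeros_like(n_p1)
        unknown = 0
        for row in long_df.itertuples(index=False):
            j = site_key.get((row.chrom, row.pos))
            if j is None:
                unknown += 1
                continue
            i = seg_key[row.segregant]
            n_p1[i, j] += int(row.n_p1)
            n_p2[i, j] += int(row.n_p2)
            n_other[i, j] += int(getattr(row, "n_other", 0))
        if unknown:
            warnings.warn(f"{unknown} count rows at sites absent from the variant "
                          "table were ignored", stacklevel=2)
        return cls(variants=variants.reset_index(drop=True), segregants=segs,
                   n_p1=n_p1, n_p2=n_p2, n_other=n_other)


@dataclass
class GenotypeMatrix:
    """Segregants x markers calls (0=P1, 1=P2, -1=missing) plus marker metadata.

    ``markers`` carries chrom, pos and - once :func:`build_marker_map` has run -
    per-marker call counts, the 1:1 chi-square p-value and a filter ``status``
    in {"pass", "distorted", "sparse", "thinned"}. Only "pass" markers feed the
    genome scan.
    """

    calls: np.ndarray
    segregants: list[str]
    markers: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.segregants), len(self.markers)):
            raise ValueError("calls shape does not match segregants x markers")
        bad = ~np.isin(self.calls, (P1, P2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be P1, P2 or missing")

    @property
    def n_segregants(self) -> int:
        return len(self.segregants)

    @property
    def marker_ids(self) -> pd.Series:
        return self.markers["chrom"].astype(str) + ":" + self.markers["pos"].astype(str)

    def pass_mask(self) -> np.ndarray:
        if "status" in self.markers.columns:
            return (self.markers["status"] == "pass").to_numpy()
        return np.ones(len(self.markers), dtype=bool)

    def subset_markers(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(calls=self.calls[:, mask], segregants=list(self.segregants),
                              markers=self.markers.loc[mask].reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        lab = np.vectorize(CALL_LABELS.get)(self.calls)
        return pd.DataFrame(lab, index=pd.Index(self.segregants, name="segregant"),
                            columns=self.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, markers: pd.DataFrame | None = None) -> "GenotypeMatrix":
        calls = frame.map(lambda v: _LABEL_CODES.get(v, MISSING)).to_numpy(dtype=np.int8)
        if markers is None:
            chrom_pos = [c.rsplit(":", 1) for c in frame.columns]
            markers = pd.DataFrame({"chrom": [c for c, _ in chrom_pos],
                                    "pos": [int(p) for _, p in chrom_pos]})
        return cls(calls=calls, segregants=list(frame.index), markers=markers.reset_index(drop=True))


def _check_parent_table(variants: pd.DataFrame, name: str) -> pd.DataFrame:
    req = {"chrom", "pos", "ref", "alt"}
    if not req.issubset(variants.columns):
        raise ValueError(f"{name} variant table needs columns {sorted(req)}")
    dup = variants.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        conflict = variants.loc[dup].groupby(["chrom", "pos"]).agg(
            n_ref=("ref", "nunique"), n_alt=("alt", "nunique"))
        if ((conflict["n_ref"] > 1) | (conflict["n_alt"] > 1)).any():
            raise ValueError(f"conflicting duplicate records in {name} variant list")
        variants = variants.drop_duplicates(subset=["chrom", "pos"])
    return variants


def distinguishing_snps(p1_variants: pd.DataFrame, p2_variants: pd.DataFrame) -> pd.DataFrame:
    """Sites where the two homozygous parents carry different alleles.

    Both inputs are per-parent homozygous SNP lists against the same reference
    (columns chrom, pos, ref, alt). A site is retained when exactly one parent
    differs from the reference (the other parent's allele is then the
    reference base) or when both differ with *different* alternate alleles;
    sites where the parents share the same variant carry no linkage
    information and are dropped.
    """
    p1 = _check_parent_table(p1_variants, "P1")
    p2 = _check_parent_table(p2_variants, "P2")
    merged = p1.merge(p2, on=["chrom", "pos"], how="outer", suffixes=("_1", "_2"))
    both = merged["alt_1"].notna() & merged["alt_2"].notna()
    ref_conflict = both & (merged["ref_1"] != merged["ref_2"])
    if ref_conflict.any():
        raise ValueError("parents report different reference alleles at shared sites")
    keep = merged[~(both & (merged["alt_1"] == merged["alt_2"]))].copy()
    ref = keep["ref_1"].where(keep["ref_1"].notna(), keep["ref_2"])
    out = pd.DataFrame({
        "chrom": keep["chrom"],
        "pos": keep["pos"].astype(int),
        "ref": ref,
        "p1_allele": keep["alt_1"].where(keep["alt_1"].notna(), ref),
        "p2_allele": keep["alt_2"].where(keep["alt_2"].notna(), ref),
    })
    bad = ~(out["p1_allele"].isin(_ALLELES) & out["p2_allele"].isin(_ALLELES))
    if bad.any():
        raise ValueError("non-ACGT allele in parental variant tables")
    return _sort_sites(out, _chrom_order(p1, p2))


def call_genotypes(counts: AlleleCountTable, variants: pd.DataFrame | None = None,
                   min_reads: int = 1, max_conflict: int = 0) -> GenotypeMatrix:
    """Assign P1/P2/missing per segregant x marker from allele read counts.

    A cell is called P1 when at least ``min_reads`` reads support the P1
    allele and at most ``max_conflict`` reads support P2 (and symmetrically
    for P2); anything else - zero coverage, too few reads, or conflicting
    support - is missing. At 3-6x coverage this prefers missingness over
    wrong calls.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if variants is not None:
        have = set(zip(counts.variants["chrom"], counts.variants["pos"]))
        want = set(zip(variants["chrom"], variants["pos"]))
        extra = have - want
        if extra:
            warnings.warn(f"{len(extra)} count sites absent from the variant table "
                          "were ignored", stacklevel=2)
            mask = np.array([k not in extra for k in
                             zip(counts.variants["chrom"], counts.variants["pos"])])
            counts = AlleleCountTable(
                variants=counts.variants.loc[mask].reset_index(drop=True),
                segregants=counts.segregants,
                n_p1=counts.n_p1[:, mask], n_p2=counts.n_p2[:, mask],
                n_other=counts.n_other[:, mask])
    p1_ok = (counts.n_p1 >= min_reads) & (counts.n_p2 <= max_conflict)
    p2_ok = (counts.n_p2 >= min_reads) & (counts.n_p1 <= max_conflict)
    calls = np.full(counts.n_p1.shape, MISSING, dtype=np.int8)
    calls[p1_ok & ~p2_ok] = P1
    calls[p2_ok & ~p1_ok] = P2
    return GenotypeMatrix(calls=calls, segregants=list(counts.segregants),
                          markers=counts.variants[["chrom", "pos"]].copy())


def chi_square_1to1(n_p1, n_p2):
    """Goodness-of-fit p-value against 1:1 segregation (df=1, no continuity
    correction), computed on non-missing calls only."""
    a = np.asarray(n_p1, dtype=float)
    b = np.asarray(n_p2, dtype=float)
    n = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(n > 0, (a - b) ** 2 / np.where(n > 0, n, 1), np.nan)
    return chi2.sf(stat, df=1)


def build_marker_map(gm: GenotypeMatrix, alpha: float = 0.05,
                     max_missing_frac: float = 0.5,
                     spacing_kb: float = 15.0) -> GenotypeMatrix:
    """Flag distorted / sparse markers and thin the rest to one per window.

    * ``sparse``: missing in more than ``max_missing_frac`` of segregants
      (a usable marker must be callable in at least half the progeny).
    * ``distorted``: chi-square 1:1 test on the non-missing calls rejects at
      level ``alpha`` (p <= alpha).
    * ``thinned``: within each half-open window [start, start + spacing_kb kb)
      per chromosome only the marker with the fewest missing calls is kept
      (ties broken leftmost).
    * ``pass``: everything that survives; only these feed the scan.

    Raises if no marker passes, reporting the per-flag counts.
    """
    if len(gm.markers) == 0:
        raise ValueError("empty genotype matrix")
    n_seg = gm.n_segregants
    n_p1 = (gm.calls == P1).sum(axis=0)
    n_p2 = (gm.calls == P2).sum(axis=0)
    n_missing = n_seg - n_p1 - n_p2
    pvals = chi_square_1to1(n_p1, n_p2)

    status = np.full(len(gm.markers), "pass", dtype=object)
    sparse = n_missing / n_seg > max_missing_frac
    status[sparse] = "sparse"
    distorted = ~sparse & (np.nan_to_num(pvals, nan=0.0) <= alpha)
    status[distorted] = "distorted"

    window = int(round(spacing_kb * 1000))
    markers = gm.markers
    candidate = status == "pass"
    for chrom in markers["chrom"].unique():
        on_chrom = (markers["chrom"] == chrom).to_numpy() & candidate
        idx = np.nonzero(on_chrom)[0]
        if len(idx) == 0:
            continue
        win_id = (markers["pos"].to_numpy()[idx] - 1) // window
        for w in np.unique(win_id):
            members = idx[win_id == w]
            keep = members[int(np.argmin(n_missing[members]))]  # first = leftmost on ties
            for m in members:
                if m != keep:
                    status[m] = "thinned"

    meta = markers.copy()
    meta["n_p1"] = n_p1
    meta["n_p2"] = n_p2
    meta["n_missing"] = n_missing
    meta["chi2_p"] = pvals
    meta["status"] = status
    if not (status == "pass").any():
        counts = pd.Series(status).value_counts().to_dict()
        raise ValueError(f"all markers filtered out: {counts}")
    return replace(gm, markers=meta)
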