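"""End-to-end orchestration: simulate -> kinetics -> genotype -> map -> scan -> stats.

Each stage reads its inputs from disk and writes its outputs with a
provenance header (package version, config hash, seed), so re-running a
single stage from the on-disk intermediates reproduces the full-pipeline
result for that stage, and a fixed seed makes the whole bundle byte-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, genetics_stats, io, kinetics, linkage, synthetic_data
from .config import PipelineConfig
from .genotyping import build_marker_map, call_genotypes

__all__ = ["run_pipeline", "validate_inputs", "ValidationEntry"]

log = logging.getLogger("fermqtl")

PARENT_STRAINS = ("P1", "P2")
HYBRID_STRAIN = "HYBRID"


def _provenance(cfg: PipelineConfig) -> list[str]:
    return [f"fermqtl {__version__}", f"config {cfg.config_hash()}", f"seed {cfg.seed}"]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the map of written outputs."""
    cfg.check_inputs()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    written: dict[str, Path] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if "simulate" in cfg.stages:
            _stage_simulate(cfg, out, prov, written)
        if "kinetics" in cfg.stages:
            _stage_kinetics(cfg, out, prov, written)
        if "genotype" in cfg.stages:
            _stage_genotype(cfg, out, prov, written)
        if "map" in cfg.stages:
            _stage_map(cfg, out, prov, written)
        if "scan" in cfg.stages:
            _stage_scan(cfg, out, prov, written)
        if "stats" in cfg.stages:
            _stage_stats(cfg, out, prov, written)
    finally:
        log.removeHandler(handler)
        handler.close()
    return written


def _stage_simulate(cfg, out, prov, written):
    genome = cfg.genome.build()
    arch = cfg.simulate.build_architecture()
    arch.validate_against(genome)
    seed = cfg.seed
    parents = synthetic_data.simulate_parents(genome, cfg.simulate.n_snps, seed)
    cross = synthetic_data.simulate_cross(parents, cfg.simulate.n_segregants, genome, seed)
    counts = synthetic_data.simulate_reads(cross, cfg.simulate.mean_coverage,
                                           cfg.simulate.error_rate, seed)
    phen = synthetic_data.simulate_phenotypes(
        cross, arch, cfg.simulate.build_design(cfg.kinetics), seed)

    io.write_variants_tsv(parents, out / "parents.tsv", header=prov)
    io.write_parents_vcf(parents, out / "parents.vcf", contigs=genome.chromosomes,
                         header=prov)
    io.write_counts_tsv(counts, out / "counts.tsv", header=prov)
    io.write_curves_csv(phen.curves, out / "curves.csv", header=prov)
    io.write_table(phen.traits, out / "true_traits.tsv", header=prov)
    truth = {"loci": phen.loci.to_dict("records"),
             "params_5pl": phen.params,
             "haplotypes": {s: "".join(map(str, row))
                            for s, row in zip(cross.segregants, cross.haplotypes)}}
    io.write_json(truth, out / "truth.json",
                  provenance={"version": __version__, "seed": cfg.seed})
    for name in ("parents.tsv", "parents.vcf", "counts.tsv", "curves.csv",
                 "true_traits.tsv", "truth.json"):
        written[name] = out / name
    log.info("simulate: %d sites, %d segregants, %d planted loci",
             len(parents), len(cross.segregants), len(phen.loci))


def _stage_kinetics(cfg, out, prov, written):
    curves_path = cfg.kinetics.curves or out / "curves.csv"
    curves = io.read_curves_csv(curves_path)
    per_rep, _ = kinetics.fit_curves_table(
        curves, t_ref_c=cfg.kinetics.t_ref_c, vant_hoff_k=cfg.kinetics.vant_hoff_k,
        thresholds=tuple(cfg.kinetics.thresholds))
    strains = kinetics.aggregate_traits(per_rep)
    io.write_table(per_rep, out / "traits_replicates.tsv", header=prov)
    io.write_table(strains, out / "traits.tsv", header=prov)
    written["traits_replicates.tsv"] = out / "traits_replicates.tsv"
    written["traits.tsv"] = out / "traits.tsv"
    log.info("kinetics: %d curves fitted, %d converged",
             len(per_rep), int(per_rep["converged"].sum()))


def _stage_genotype(cfg, out, prov, written):
    variants = io.read_variants_tsv(cfg.genotype.variants or out / "parents.tsv")
    counts = io.read_counts_tsv(cfg.genotype.counts or out / "counts.tsv", variants)
    gm = call_genotypes(counts, min_reads=cfg.genotype.min_reads,
                        max_conflict=cfg.genotype.max_conflict)
    io.write_genotype_matrix(gm, out / "genotypes.tsv", out / "markers.tsv", header=prov)
    written["genotypes.tsv"] = out / "genotypes.tsv"
    written["markers.tsv"] = out / "markers.tsv"
    log.info("genotype: %d segregants x %d markers, %.1f%% missing",
             gm.n_segregants, len(gm.markers),
             100.0 * float((gm.calls == -1).mean()))


def _stage_map(cfg, out, prov, written):
    gm = io.read_genotype_matrix(out / "genotypes.tsv")
    gm = build_marker_map(gm, alpha=cfg.genotype.alpha,
                          max_missing_frac=cfg.genotype.max_missing_frac,
                          spacing_kb=cfg.genotype.spacing_kb)
    io.write_genotype_matrix(gm, out / "genotypes.tsv", out / "markers.tsv", header=prov)
    counts = gm.markers["status"].value_counts().to_dict()
    log.info("map: marker filters %s", counts)
    written["markers.tsv"] = out / "markers.tsv"


def _stage_scan(cfg, out, prov, written):
    gm = io.read_genotype_matrix(out / "genotypes.tsv", out / "markers.tsv")
    traits = io.read_table(out / "traits.tsv").set_index("strain")
    seg_traits = traits.loc[[s for s in gm.segregants if s in traits.index]]
    all_calls = []
    for trait in cfg.scan.traits:
        y = seg_traits[trait].reindex(gm.segregants)
        profile = linkage.wilcoxon_scan(gm, y, trait_name=trait,
                                        min_group=cfg.scan.min_group)
        null = linkage.permutation_threshold(gm, y, n_perm=cfg.scan.n_perm,
                                             alpha=cfg.scan.alpha, seed=cfg.seed or 0,
                                             trait_name=trait,
                                             min_group=cfg.scan.min_group)
        calls = linkage.call_qtl(profile, null, drop=cfg.scan.drop)
        io.write_table(profile.table, out / f"scan_{trait}.tsv", header=prov)
        io.write_table(pd.DataFrame({"max_lk": null.max_lk}),
                       out / f"null_{trait}.tsv", header=prov)
        all_calls.extend(c.as_dict() for c in calls)
        log.info("scan %s: threshold %.3f, %d QTL", trait, null.threshold(), len(calls))
        written[f"scan_{trait}.tsv"] = out / f"scan_{trait}.tsv"
        written[f"null_{trait}.tsv"] = out / f"null_{trait}.tsv"
    io.write_json({"calls": all_calls}, out / "qtl_calls.json",
                  provenance={"version": __version__, "seed": cfg.seed})
    written["qtl_calls.json"] = out / "qtl_calls.json"


def _env_sd_per_trait(per_rep: pd.DataFrame, trait_names) -> dict[str, float]:
    """Pooled within-strain replicate SD per trait."""
    out = {}
    for t in trait_names:
        if t not in per_rep.columns:
            continue
        var_w = per_rep.groupby("strain")[t].var(ddof=1).dropna()
        out[t] = float(np.sqrt(var_w.mean())) if len(var_w) else float("nan")
    return out


def _stage_stats(cfg, out, prov, written):
    per_rep = io.read_table(out / "traits_replicates.tsv")
    traits = io.read_table(out / "traits.tsv").set_index("strain")
    trait_names = [c for c in ("Pmax", "rate", "t0.5", "t2", "t5") if c in traits.columns]
    env_sd = _env_sd_per_trait(per_rep, trait_names)

    seg_names = [s for s in traits.index
                 if s not in PARENT_STRAINS and s != HYBRID_STRAIN]
    seg_traits = traits.loc[seg_names, trait_names]
    report: dict = {"env_sd": env_sd}
    if all(p in traits.index for p in PARENT_STRAINS) and HYBRID_STRAIN in traits.index:
        parent_means = traits.loc[list(PARENT_STRAINS), trait_names]
        hybrid = traits.loc[HYBRID_STRAIN, trait_names]
        summary = genetics_stats.genetics_report(
            seg_traits, parent_means, hybrid, env_sd,
            trait_names=trait_names, k=cfg.stats.k_transgression)
        io.write_table(summary, out / "cross_summary.tsv", header=prov)
        written["cross_summary.tsv"] = out / "cross_summary.tsv"
        report["cross_summary"] = summary.to_dict("records")

    calls_path = out / "qtl_calls.json"
    if calls_path.exists():
        calls = io.read_json(calls_path)["calls"]
        peaks = _top_peak_markers(calls, max_markers=3)
        if len(peaks) >= 2:
            gm = io.read_genotype_matrix(out / "genotypes.tsv", out / "markers.tsv")
            marker_ids = list(gm.marker_ids)
            cols = [marker_ids.index(p) for p in peaks if p in marker_ids]
            geno = gm.calls[:, cols].astype(float)
            geno[geno < 0] = np.nan
            seg_in_gm = [s for s in gm.segregants if s in seg_traits.index]
            sel = [gm.segregants.index(s) for s in seg_in_gm]
            anova_out = {}
            for t in cfg.scan.traits:
                y = seg_traits.loc[seg_in_gm, t].to_numpy()
                try:
                    dec = genetics_stats.anova_decomposition(
                        y, geno[sel], term_names=[f"QTL{i+1}" for i in range(len(cols))],
                        trait_name=t)
                except ValueError as exc:
                    log.warning("stats: ANOVA for %s skipped (%s)", t, exc)
                    continue
                anova_out[t] = {"peak_markers": peaks,
                                "terms": dec.table.to_dict("records"),
                                "explained_pct": dec.explained_pct,
                                "levene_p": dec.levene_p, "shapiro_p": dec.shapiro_p}
            report["anova"] = anova_out
            report["duncan"] = _haplotype_duncan(gm, seg_traits, seg_in_gm, sel,
                                                 cols, cfg.scan.traits)
    io.write_json(report, out / "report.json",
                  provenance={"version": __version__, "seed": cfg.seed})
    written["report.json"] = out / "report.json"
    log.info("stats: report written (%d traits)", len(trait_names))


def _top_peak_markers(calls: list[dict], max_markers: int = 3) -> list[str]:
    seen = {}
    for c in sorted(calls, key=lambda c: -c["peak_lk"]):
        seen.setdefault(c["peak_marker"], None)
    return list(seen)[:max_markers]


def _haplotype_duncan(gm, seg_traits, seg_in_gm, sel, cols, scan_traits) -> dict:
    """Duncan letters for trait means grouped by the peak-marker haplotype string."""
    out = {}
    codes = gm.calls[np.ix_(sel, cols)]
    labels = ["".join("12?"[c] if c >= 0 else "?" for c in row) for row in codes]
    hap = pd.Series(labels, index=seg_in_gm)
    hap = hap[~hap.str.contains(r"\?")]
    for t in scan_traits:
        y = seg_traits.loc[hap.index, t]
        grp = y.groupby(hap)
        means = grp.mean()
        sizes = grp.size()
        keep = sizes >= 2
        if keep.sum() < 2:
            continue
        means, sizes = means[keep], sizes[keep]
        groups = [y[hap == h].to_numpy() for h in means.index]
        n_tot = int(sum(len(g) for g in groups))
        mse = float(np.sum([(len(g) - 1) * np.var(g, ddof=1) for g in groups]) /
                    (n_tot - len(groups)))
        if mse <= 0:
            continue
        letters = genetics_stats.duncan_groups(means.to_numpy(), sizes.to_numpy(),
                                               mse, n_tot - len(groups))
        out[t] = {"classes": list(means.index), "n": sizes.tolist(),
                  "means": [float(m) for m in means], "letters": letters}
    return out


# ---------------------------------------------------------------------------
# input validation

class ValidationEntry(dict):
    """One per-file validation result: file, format, ok, message, line."""


def validate_inputs(entries) -> list[ValidationEntry]:
    """Check input files against their declared formats.

    ``entries`` is an iterable of (path, format) with format one of
    "curves", "counts", "variants", "genotypes", "traits". Unreadable or
    malformed files produce a fail entry (with the 1-based line number of the
    first violation where applicable) rather than an exception.
    """
    report = []
    for path, fmt in entries:
        entry = ValidationEntry(file=str(path), format=fmt, ok=True, message="ok",
                                line=None)
        try:
            checker = _CHECKERS[fmt]
        except KeyError:
            entry.update(ok=False, message=f"unknown format {fmt!r}")
            report.append(entry)
            continue
        try:
            problem = checker(path)
        except Exception as exc:  # noqa: BLE001 - must not crash on bad files
            problem = (f"unreadable: {exc}", None)
        if problem is not None:
            entry.update(ok=False, message=problem[0], line=problem[1])
        report.append(entry)
    return report


def _data_lines(path, sep):
    """Yield (line_number, fields) for non-comment lines, header included."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            yield i, raw.rstrip("\n").split(sep)


def _check_columns(fields, required):
    missing = [c for c in required if c not in fields]
    return f"missing columns {missing}" if missing else None


def _check_curves(path):
    rows = _data_lines(path, ",")
    try:
        _, header = next(rows)
    except StopIteration:
        return ("empty file", None)
    req = ["strain", "replicate", "time_days", "pressure_bar", "temperature_C"]
    msg = _check_columns(header, req)
    if msg:
        return (msg, None)
    idx = {c: header.index(c) for c in req}
    last_time: dict[tuple, float] = {}
    for lineno, fields in rows:
        try:
            t = float(fields[idx["time_days"]])
            p = float(fields[idx["pressure_bar"]])
        except (ValueError, IndexError):
            return ("non-numeric time or pressure", lineno)
        if p < 0:
            return ("negative pressure", lineno)
        key = (fields[idx["strain"]], fields[idx["replicate"]])
        if key in last_time and t <= last_time[key]:
            return (f"non-increasing time within replicate {key}", lineno)
        last_time[key] = t
    return None


def _check_counts(path):
    rows = _data_lines(path, "\t")
    try:
        _, header = next(rows)
    except StopIteration:
        return ("empty file", None)
    msg = _check_columns(header, ["segregant", "chrom", "pos", "n_p1", "n_p2"])
    if msg:
        return (msg, None)
    idx = [header.index(c) for c in ("pos", "n_p1", "n_p2")]
    for lineno, fields in rows:
        try:
            vals = [int(fields[i]) for i in idx]
        except (ValueError, IndexError):
            return ("non-integer position or count", lineno)
        if vals[1] < 0 or vals[2] < 0:
            return ("negative read count", lineno)
        if vals[0] < 1:
            return ("position must be 1-based positive", lineno)
    return None


def _check_variants(path):
    rows = _data_lines(path, "\t")
    try:
        _, header = next(rows)
    except StopIteration:
        return ("empty file", None)
    msg = _check_columns(header, ["chrom", "pos", "ref", "p1_allele", "p2_allele"])
    if msg:
        return (msg, None)
    i1, i2 = header.index("p1_allele"), header.index("p2_allele")
    for lineno, fields in rows:
        if fields[i1] not in "ACGT" or fields[i2] not in "ACGT":
            return ("non-ACGT allele", lineno)
        if fields[i1] == fields[i2]:
            return ("identical parental alleles", lineno)
    return None


def _check_genotypes(path):
    rows = _data_lines(path, "\t")
    try:
        _, header = next(rows)
    except StopIteration:
        return ("empty file", None)
    if header[0] != "segregant":
        return ("first column must be 'segregant'", None)
    for lineno, fields in rows:
        bad = [v for v in fields[1:] if v not in ("P1", "P2", "NA", "")]
        if bad:
            return (f"invalid genotype value {bad[0]!r}", lineno)
    return None


def _check_traits(path):
    rows = _data_lines(path, "\t")
    try:
        _, header = next(rows)
    except StopIteration:
        return ("empty file", None)
    if "strain" not in header:
        return ("missing column 'strain'", None)
    return None


_CHECKERS = {
    "curves": _check_curves,
    "counts": _check_counts,
    "variants": _check_variants,
    "genotypes": _check_genotypes,
    "traits": _check_traits,
}
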