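"""Readers and writers for the pipeline's plain-text formats.

All tabular files are TSV/CSV with optional leading ``#`` provenance lines;
parental variants can additionally be written as a two-sample VCF and read
back (per parent) with cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyping import AlleleCountTable, GenotypeMatrix

__all__ = [
    "write_table", "read_table",
    "write_variants_tsv", "read_variants_tsv",
    "write_parents_vcf", "read_vcf_variants",
    "write_counts_tsv", "read_counts_tsv",
    "write_genotype_matrix", "read_genotype_matrix",
    "write_curves_csv", "read_curves_csv",
    "write_json", "read_json",
    "read_gff3_genes",
]


def _open_header(path, header):
    lines = [f"# {h}" for h in (header or [])]
    return ("\n".join(lines) + "\n") if lines else ""


def write_table(df: pd.DataFrame, path, sep="\t", header=None, float_fmt="%.6g"):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_open_header(path, header))
        df.to_csv(fh, sep=sep, index=False, float_format=float_fmt)


def read_table(path, sep="\t", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def write_variants_tsv(variants: pd.DataFrame, path, header=None):
    cols = ["chrom", "pos", "ref", "p1_allele", "p2_allele"]
    write_table(variants[cols], path, header=header)


def read_variants_tsv(path) -> pd.DataFrame:
    df = read_table(path)
    df["pos"] = df["pos"].astype(int)
    return df


def write_parents_vcf(variants: pd.DataFrame, path, p1_name="P1", p2_name="P2",
                      contigs=None, header=None):
    """Write the distinguishing sites as a minimal VCF with two homozygous samples."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for h in header or []:
        lines.append(f"##fermqtl={h}")
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{p1_name}\t{p2_name}")
    for row in variants.itertuples(index=False):
        alts = []
        def gt(allele):
            if allele == row.ref:
                return "0/0"
            if allele not in alts:
                alts.append(allele)
            return f"{alts.index(allele) + 1}/{alts.index(allele) + 1}"
        g1, g2 = gt(row.p1_allele), gt(row.p2_allele)
        alt_field = ",".join(alts) if alts else "."
        lines.append(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alt_field}\t.\tPASS\t.\tGT\t{g1}\t{g2}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_variants(path, sample: str) -> pd.DataFrame:
    """Homozygous non-reference calls of one sample as (chrom, pos, ref, alt) rows."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in VCF ({vcf.samples})")
    si = vcf.samples.index(sample)
    rows = []
    for var in vcf:
        gt = var.genotypes[si]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if not alleles or any(a != alleles[0] for a in alleles):
            continue  # missing or heterozygous
        if alleles[0] == 0:
            continue  # reference call
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[alleles[0] - 1]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_counts_tsv(counts: AlleleCountTable, path, header=None):
    write_table(counts.to_long(), path, header=header)


def read_counts_tsv(path, variants: pd.DataFrame) -> AlleleCountTable:
    long_df = read_table(path)
    long_df["pos"] = long_df["pos"].astype(int)
    return AlleleCountTable.from_long(long_df, variants)


def write_genotype_matrix(gm: GenotypeMatrix, calls_path, markers_path=None, header=None):
    frame = gm.to_frame().reset_index()
    write_table(frame, calls_path, header=header)
    if markers_path is not None:
        write_table(gm.markers, markers_path, header=header)


def read_genotype_matrix(calls_path, markers_path=None) -> GenotypeMatrix:
    frame = read_table(calls_path, dtype=str).set_index("segregant")
    frame = frame.fillna("NA")
    markers = None
    if markers_path is not None:
        markers = read_table(markers_path)
        markers["pos"] = markers["pos"].astype(int)
    return GenotypeMatrix.from_frame(frame, markers)


def write_curves_csv(curves: pd.DataFrame, path, header=None):
    cols = ["strain", "replicate", "time_days", "pressure_bar", "temperature_C"]
    write_table(curves[cols], path, sep=",", header=header)


def read_curves_csv(path) -> pd.DataFrame:
    return read_table(path, sep=",")


def write_json(obj, path, provenance: dict | None = None):
    if provenance and isinstance(obj, dict):
        obj = {"_provenance": provenance, **obj}
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=False, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_gff3_genes(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene intervals (gene_id, chrom, start, end; 1-based inclusive) from a GFF3."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature_type:
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id")
            rows.append((gene_id, parts[0], int(parts[3]), int(parts[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
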