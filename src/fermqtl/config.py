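"""Pipeline configuration: one JSON document, flat per-stage namespaces."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .synthetic_data import (GenomeModel, Locus, MeasurementDesign, QtlArchitecture,
                             default_architecture, default_genome)

__all__ = ["PipelineConfig", "demo_config", "STAGES"]

STAGES = ("simulate", "kinetics", "genotype", "map", "scan", "stats")


class GenomeConfig(BaseModel):
    chromosomes: list[tuple[str, int]] | None = None
    cm_per_kb: float = 0.4

    def build(self) -> GenomeModel:
        if self.chromosomes is None:
            return default_genome(self.cm_per_kb)
        return GenomeModel(chromosomes=tuple((n, int(l)) for n, l in self.chromosomes),
                           cm_per_kb=self.cm_per_kb)


class LocusConfig(BaseModel):
    chrom: str
    pos: int
    trait: str
    effect: float
    beneficial: str = "P2"


class SimulateConfig(BaseModel):
    n_snps: int = 1071
    n_segregants: int = 117
    mean_coverage: float = 4.5
    error_rate: float = 0.002
    n_replicates: int = 2
    time_step_days: float = 1.0
    time_max_days: float = 40.0
    replicate_sd: float = 0.05
    loci: list[LocusConfig] | None = None

    def build_architecture(self) -> QtlArchitecture:
        if self.loci is None:
            arch = default_architecture()
        else:
            arch = QtlArchitecture(loci=[Locus(**lc.model_dump()) for lc in self.loci])
        arch.replicate_sd = self.replicate_sd
        return arch

    def build_design(self, kin: "KineticsConfig") -> MeasurementDesign:
        return MeasurementDesign(
            times=np.arange(0.0, self.time_max_days + 1e-9, self.time_step_days),
            thresholds=tuple(kin.thresholds), t_ref_c=kin.t_ref_c,
            vant_hoff_k=kin.vant_hoff_k, n_replicates=self.n_replicates)


class KineticsConfig(BaseModel):
    t_ref_c: float = 10.0
    vant_hoff_k: float = 2400.0
    thresholds: list[float] = Field(default_factory=lambda: [0.5, 2.0, 5.0])
    curves: str | None = None  # input path when the simulate stage is off


class GenotypeConfig(BaseModel):
    min_reads: int = 1
    max_conflict: int = 0
    alpha: float = 0.05
    max_missing_frac: float = 0.5
    spacing_kb: float = 15.0
    variants: str | None = None
    counts: str | None = None


class ScanConfig(BaseModel):
    traits: list[str] = Field(default_factory=lambda: ["rate", "t2", "t5"])
    n_perm: int = 1000
    alpha: float = 0.05
    min_group: int = 10
    drop: float = 1.0


class StatsConfig(BaseModel):
    k_transgression: float = 2.0
    gxe_csv: str | None = None


class PipelineConfig(BaseModel):
    """Everything one run needs; validates stage wiring up front."""

    outdir: str
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    seed: int | None = None
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    genotype: GenotypeConfig = Field(default_factory=GenotypeConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @model_validator(mode="after")
    def _check(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "simulate" in self.stages and self.seed is None:
            raise ValueError("field 'seed' is required when the simulate stage is enabled")
        return self

    def check_inputs(self) -> None:
        """Verify that externally supplied input files exist for enabled stages."""
        outdir = Path(self.outdir)
        def need(stage, attr, default_name):
            path = getattr(getattr(self, stage if stage != "map" else "genotype"),
                           attr, None)
            if path is None:
                path = outdir / default_name
            if "simulate" in self.stages and attr in ("curves", "variants", "counts"):
                return  # produced upstream
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs input '{attr}' but {path} does not exist")
        if "kinetics" in self.stages:
            need("kinetics", "curves", "curves.csv")
        if "genotype" in self.stages:
            need("genotype", "variants", "parents.tsv")
            need("genotype", "counts", "counts.tsv")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location and stage
        selection excluded, so reruns and partial reruns agree)."""
        payload = self.model_dump(exclude={"outdir", "stages"})
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1) + "\n")


def demo_config(outdir, seed: int = 7, n_perm: int = 200) -> PipelineConfig:
    """The bundled end-to-end demonstration: default cross, reduced permutations."""
    return PipelineConfig(outdir=str(outdir), seed=seed,
                          scan=ScanConfig(n_perm=n_perm))
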