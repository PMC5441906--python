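"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-environment metabolome study.

    Defaults emulate a 135-line elite winter-wheat panel with family
    structure, genotyped at a few thousand post-QC biallelic SNPs and
    phenotyped for 76 metabolite traits at 3 locations with 2 replicates
    laid out in incomplete blocks.  Genotype-by-environment variance
    defaults to twice the genotypic variance, so single-site data are
    noisy relative to the genetic signal (entry-mean heritability around
    0.5 at these settings; real panels spread widely around their mean).

    ``dag_edges`` is a list of ``(parent, child, path coefficient)``
    trait triples defining a linear causal DAG among trait genetic
    values.  ``qtl_map`` is a list of ``(trait, snp_index, effect)``
    with the effect expressed in genetic-standard-deviation units per
    standardized dosage unit, so a QTL with effect b explains
    b^2 / (1 + b^2) of its trait's direct genotypic variance.
    """

    n_lines: int = 135
    n_families: int = 15
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    het_rate: float = 0.01
    n_envs: int = 3
    n_reps: int = 2
    n_blocks_per_rep: int = 5
    n_traits: int = 76
    dag_edges: list[tuple[str, str, float]] = field(default_factory=list)
    qtl_map: list[tuple[str, int, float]] = field(default_factory=list)
    var_G: float = 1.0
    var_GxE: float = 2.0
    var_resid: float = 1.0
    env_effect_sd: float = 3.0
    block_sd: float = 0.5
    heading_date_sd: float = 3.0
    polygenic: str = "genomic"  # "genomic" (u ~ N(0, var_G * K)) or "iid"
    # optional [start, stop) SNP index range backing the genomic polygenic
    # term; None = all SNPs.  A scan over SNPs outside the range then tests
    # markers that are null yet share the panel's family structure.
    polygenic_snps: tuple[int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        for name in ("missing_rate", "het_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} is not a probability")
        if self.n_families > self.n_lines:
            raise ValueError("n_families cannot exceed n_lines")
        if self.n_families < 1 or self.n_lines < 2:
            raise ValueError("need at least 1 family and 2 lines")
        for name in ("var_G", "var_GxE", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.polygenic not in ("genomic", "iid"):
            raise ValueError("polygenic must be 'genomic' or 'iid'")
        for trait, snp, _ in self.qtl_map:
            if not (0 <= int(snp) < self.n_snps):
                raise ValueError(f"qtl_map snp index {snp} out of range for trait {trait}")


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    FDR is controlled at 0.20 for reporting mQTL and at the stricter
    0.10 for the anchors fed to the network-orientation stage.
    """

    outdir: str = "mqtlnet_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    genotype_path: str | None = None
    phenotype_path: str | None = None
    max_missing: float = 0.05
    max_het: float = 0.05
    min_maf: float = 0.05
    cv_filter: float | None = None
    boxcox: bool = False
    fdr_report: float = 0.20
    fdr_network: float = 0.10
    varcomp_alpha: float = 0.05
    alpha_skeleton: float = 0.01
    alpha_orient: float = 0.05
    snpxe: str = "significant"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "qc", "trial", "corr", "gwas", "network"]
    )
    force: bool = False

    def validate(self) -> None:
        for name in ("max_missing", "max_het", "min_maf", "fdr_report",
                     "fdr_network", "varcomp_alpha", "alpha_skeleton", "alpha_orient"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0,1]")
        self.sim.validate()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    sim_raw = raw.pop("sim", {})
    if "dag_edges" in sim_raw:
        sim_raw["dag_edges"] = [tuple(e) for e in sim_raw["dag_edges"]]
    if "qtl_map" in sim_raw:
        sim_raw["qtl_map"] = [tuple(e) for e in sim_raw["qtl_map"]]
    if "maf_range" in sim_raw:
        sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
    cfg = RunConfig(sim=SimConfig(**sim_raw), **raw)
    cfg.validate()
    return cfg
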