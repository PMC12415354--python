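"""Flat key-value pipeline configuration (YAML-serialisable)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with documented defaults.

    Thresholds follow the reference analysis where one is printed
    (2000 consensus iterations, DEG regimes adj p < 0.01 and
    |log2FC| > 1 with FDR < 0.05, bootstrap 1000 x 70/30, association
    filter |rho| >= 0.20 with p < 0.05); the remaining defaults are the
    package's own documented choices.
    """

    # inputs: either file paths ...
    expression: str | None = None
    expression_unit: str = "log2TPM1"
    clinical: str | None = None
    gmt: str | None = None
    mutations: str | None = None
    # ... or the synthetic generator
    simulate: bool = False
    sim_n_samples: int = 500
    sim_delta: float = 2.0
    sim_hazard_beta: float = 1.0
    sim_censoring_rate: float = 0.3

    # regulator panel (None -> built-in 23-gene panel)
    regulators: list[str] | None = None

    # consensus clustering
    consensus_iterations: int = 2000
    consensus_fraction: float = 0.8
    pattern_k_min: int = 2
    pattern_k_max: int = 4
    genecluster_k_min: int = 2
    genecluster_k_max: int = 4
    delta_area_threshold: float = 0.05

    # differential expression
    deg_mode: str = "phenotype"

    # enrichment
    ssgsea_alpha: float = 0.25
    ssgsea_normalization: str = "none"

    # signature / score
    cox_p_threshold: float = 0.05
    score_formula: str = "auto"      # auto | A | B
    bootstrap_iterations: int = 1000
    bootstrap_split: float = 0.7

    # stratification & associations
    cutpoint_minprop: float = 0.1
    rho_threshold: float = 0.20
    assoc_p_threshold: float = 0.05

    # mutations
    tmb_mode: str = "count"
    exome_mb: float = 38.0

    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return asdict(self)
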