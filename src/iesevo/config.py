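"""Pipeline configuration: schema-validated YAML with the analysis
defaults (every threshold of the comparative pipeline in one place)."""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kmer_k: int = 17
    mac_attribution_max_depth: int = 500
    irs_bin_width: float = 0.05
    weak_irs: float = 0.10                  # strict > rule
    floating_window: int = 10
    min_scaffold_kb: float = 10.0
    min_gene_reads: float = 15.0
    coverage_pct_low: float = 10.0
    coverage_pct_high: float = 90.0
    mac_variable_window: int = 2000
    mac_variable_min_region: int = 4000
    family_min_genes: int = 3
    family_min_identity: float = 0.50
    block_min_length: int = 10
    block_max_gap_fraction: float = 0.2
    block_min_column_identity: float = 0.5
    conserved_min_species: int = 5
    conserved_min_identity: float = 0.70
    allvsall_evalue: float = 1e-8
    figure_evalue: float = 1e-5
    boundary_margin_nt: int = 20
    flank_min_identity: float = 0.75
    flank_min_length: int = 150
    profile_min_members: int = 10
    scan_evalue: float = 1e-3
    extremity_tol: int = 3
    table_min_mobile: int = 10
    min_depth_density: float = 15.0
    short_ies_bp: int = 35
    long_ies_bp: int = 100
    posterior_dating_threshold: float = 0.99


class McmcSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_iter: int = 500_000
    tuning_iter: int = 10_000
    tuning_interval: int = 1_000
    thin: int = 50
    burnin_frac: float = 0.10
    root_prior: str = "stationary"


class Stages(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulate: bool = True
    ksize: bool = True
    catalog: bool = True
    infer: bool = True
    rates: bool = True
    mobile: bool = True
    report: bool = True


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    outdir: str = "iesevo_out"
    stages: Stages = Stages()
    thresholds: Thresholds = Thresholds()
    mcmc: McmcSettings = McmcSettings()
    n_families: int = 40
    dup_rate: float = 0.1
    gene_loss_rate: float = 0.0
    gain_rate_per_kb: float = 1.0
    loss_rate_per_ies: float = 0.2
    root_density_per_kb: float = 2.0
    alignment_kb: float = 1.0
    genome_scaffold_length: int = 30_000
    genome_ies_per_kb: float = 0.5
    read_depth: float = 25.0
    read_length: int = 100
    mac_contamination: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
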