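"""Structured pipeline configuration.

One YAML file is the single source of truth for every stage threshold; the
defaults are the analysis protocol's printed values (gnomAD 0.5%, depth 10,
alt reads 5, bulk log2FC 0.5 / p 0.05, correlation 0.6, template score 700,
single-cell log2FC 0.25, proportion log2FD 0.3, adjusted p 0.05, detection
fraction 5%). Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class StageParams:
    # variant filtering / tiering
    gnomad_af_max: float = 0.005
    min_depth: int = 10
    min_alt_reads: int = 5
    # bulk DEG
    bulk_log2fc: float = 0.5
    p_threshold: float = 0.05
    # networks
    r_threshold: float = 0.6
    template_min_score: int = 700
    # enrichment
    gsea_weight: float = 1.0
    n_perm: int = 1000
    min_regulon_targets: int = 5
    # single cell
    sc_log2fc: float = 0.25
    pseudobulk_log2fc: float = 0.25
    log2fd_threshold: float = 0.3
    p_adj_threshold: float = 0.05
    detection_fraction: float = 0.05
    hill_kh: float = 0.5
    n_boot: int = 1000


@dataclass
class PipelinePaths:
    out_dir: str = "results"
    panel: str | None = None
    variants: str | None = None
    bulk_counts: str | None = None
    bulk_metadata: str | None = None
    lr_pairs: str | None = None
    cytokines: str | None = None
    gene_sets: str | None = None
    regulons: str | None = None
    template: str | None = None
    sc_dir: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    paths: PipelinePaths = field(default_factory=PipelinePaths)
    params: StageParams = field(default_factory=StageParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in (("paths", PipelinePaths), ("params", StageParams)):
            sub = dict(data.get(name) or {})
            sub_known = {f.name for f in fields(sub_cls)}
            sub_unknown = set(sub) - sub_known
            if sub_unknown:
                raise ValueError(
                    f"unknown config keys under {name!r}: {sorted(sub_unknown)}"
                )
            data[name] = sub_cls(**sub)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)
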