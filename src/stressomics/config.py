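"""Structured pipeline configuration with strict validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end synthetic-study pipeline.

    Defaults are the shipped study scenario: a biological arm of 120 animals
    in 3 batches and a transcriptome arm of 30 animals in 2 batches, four
    planted kinetic clusters of sizes 18/17/8/22 at 1 log2-unit effect size
    over 900 null genes, 3 probes per gene.
    """

    seed: int = 1

    # design
    n_animals_bio: int = 120
    n_batches_bio: int = 3
    n_animals_expr: int = 30
    n_batches_expr: int = 2
    cluster_sizes: tuple = (18, 17, 8, 22)
    n_null_genes: int = 900
    probes_per_gene: int = 3
    effect_size: float = 1.0
    probe_noise_sd: float = 0.2
    n_control_probes: int = 50

    # preprocessing
    knn_k: int = 5
    knn_weighting: str = "uniform"
    outlier_z: float = 4.0
    min_expressed_fraction: float = 0.5

    # testing thresholds
    alpha: float = 0.05
    min_fraction: float = 0.75
    min_corr: float = 0.65
    bio_adjust: str = "BH"
    transcript_adjust: str = "bonferroni"

    # clustering / latent models
    k_clusters: int = 4
    distance_mode: str = "corr_rows"
    pls_mode: str = "canonical"
    n_components: int = 2
    keep_x: int = 10
    scale_bio: bool = True
    scale_expr: bool = False

    # integration
    anchor_variable: str = "cortisol"
    anchor_time: float = 1.0
    lg_log: bool = False

    # enrichment
    enrich_min_genes: int = 3
    enrich_fdr: float = 0.05

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        checks = [
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (0 < self.min_fraction <= 1, "min_fraction must lie in (0, 1]"),
            (-1 <= self.min_corr <= 1, "min_corr must lie in [-1, 1]"),
            (0 < self.enrich_fdr < 1, "enrich_fdr must lie in (0, 1)"),
            (self.knn_k >= 1, "knn_k must be >= 1"),
            (self.keep_x >= 1, "keep_x must be >= 1"),
            (self.k_clusters >= 1, "k_clusters must be >= 1"),
            (self.n_components >= 1, "n_components must be >= 1"),
            (0 <= self.min_expressed_fraction <= 1,
             "min_expressed_fraction must lie in [0, 1]"),
            (self.distance_mode in ("corr_rows", "corr_dissim"),
             "distance_mode must be 'corr_rows' or 'corr_dissim'"),
            (self.pls_mode in ("canonical", "regression"),
             "pls_mode must be 'canonical' or 'regression'"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cluster_sizes"] = list(self.cluster_sizes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
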