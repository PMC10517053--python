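"""Pipeline configuration: a flat key-value file (YAML) with strict key
validation. The resolved configuration is written next to every run's
outputs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # global
    seed: int = 0

    # input files (unused when simulate=True)
    simulate: bool = True
    otu_tsv: str | None = None
    meta_csv: str | None = None
    features_csv: str | None = None
    grid_netcdf: str | None = None

    # synthetic world
    n_samples: int = 90
    n_otus_per_module: int = 8
    n_modules: int = 3
    n_noise_otus: int = 10
    read_depth: int = 2000
    gradient_strength: float = 4.0
    feature_noise_sd: float = 0.02
    spatial_cluster_km: float = 150.0
    shallow_frac: float = 0.05
    grid_years: int = 2
    grid_rows: int = 24
    grid_cols: int = 24
    grid_trend_per_year: float = 0.0
    grid_missing_rate: float = 0.0

    # preprocessing
    rarefaction_depth: int = 1000
    bin_arcmin: float = 5.0
    min_seafloor_m: float = 200.0
    thin_min_km: float = 200.0
    otu_min_frac: float = 0.002
    otu_min_prevalence: float = 0.10
    clr_pseudocount: float = 1.0
    size_fractions: list[str] = field(default_factory=list)  # empty = keep all

    # network
    network_alpha: float = 0.05
    network_max_conditioning: int = 1
    module_algorithms: list[str] = field(default_factory=lambda: ["leiden", "louvain"])
    module_seed: int = 0
    min_module_size: int = 3

    # community typing
    sigmoid_scale: float = 1.0
    sigmoid_offset: float = 0.0

    # classifier
    classifier_algorithm: str = "svm"
    feature_set: str = "all17"
    inner_folds: int = 5
    buffer_km: float = 2000.0
    threshold_grid_start: float = 0.01
    threshold_grid_stop: float = 0.99
    threshold_grid_step: float = 0.01
    permutation_repeats: int = 5

    # gridded prediction / trends
    downsample_factor: int = 12
    trend_alpha: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
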