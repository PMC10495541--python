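"""Pipeline configuration.

All tunable thresholds of the analysis live in one place so that a run can
log a single, auditable record of its parameters.  Defaults correspond to
the published analysis protocol: binding-probability cutoffs of 0.5 (any
binding) and 0.8 (high-confidence binding), a miRNA expression-variance
floor of 0.2, removal of features absent in >=25% of samples, an 80/20
train/test split, a held-out RMSE gate of 0.7, Benjamini-Hochberg control
at alpha = 0.05, and 1000 subsampling iterations of 10 000 pairs each.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    bind_prob_high: float = 0.80
    bind_prob_low: float = 0.50
    min_mirna_variance: float = 0.2
    max_absent_fraction: float = 0.25
    top_k_mirnas: Optional[int] = None
    train_fraction: float = 0.8
    rmse_threshold: float = 0.7
    fdr_alpha: float = 0.05
    subsample_size: int = 10_000
    subsample_iterations: int = 1000
    random_seed: int = 0
    #: use |r| instead of signed r when picking the covariate miRNA
    covariate_abs_correlation: bool = False
    #: apply BH once over all pairs instead of within each subsample
    global_bh: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.bind_prob_low < self.bind_prob_high <= 1.0):
            raise ValueError(
                "require 0 < bind_prob_low < bind_prob_high <= 1, got "
                f"{self.bind_prob_low}, {self.bind_prob_high}"
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        for name in ("min_mirna_variance", "max_absent_fraction", "rmse_threshold", "fdr_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.top_k_mirnas is not None and self.top_k_mirnas <= 0:
            raise ValueError("top_k_mirnas must be positive or None")
        if self.subsample_size <= 0 or self.subsample_iterations <= 0:
            raise ValueError("subsample_size and subsample_iterations must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
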