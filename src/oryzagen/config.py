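"""Pipeline configuration.

Collects the analysis parameters in one validated record: 10 kb windows
with a 30% data-fraction rule, an 80% per-site call-rate filter, a 2%
minor-allele-frequency floor, 1 Mb LD windows summarised in 1 kb bins, a
1% fourth-gamete error tolerance, a 0.1 silhouette cutoff, a 0.1
target/control depth-ratio threshold for deletion calls, and 100-SNP f4
jackknife blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .datatypes import ValidationError


@dataclass
class PipelineConfig:
    window_size: int = 10_000
    min_window_data_fraction: float = 0.3
    min_call_rate: float = 0.8
    min_maf: float = 0.02
    ld_window: int = 1_000_000
    ld_bin: int = 1_000
    fg_error_freq: float = 0.01
    silhouette_threshold: float = 0.1
    deletion_ratio_threshold: float = 0.1
    control_min_depth: float = 1.0
    f4_block_size: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "min_window_data_fraction": self.min_window_data_fraction,
            "min_call_rate": self.min_call_rate,
            "fg_error_freq": self.fg_error_freq,
            "deletion_ratio_threshold": self.deletion_ratio_threshold,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError(f"min_maf must be in [0, 0.5], got {self.min_maf}")
        if not -1.0 <= self.silhouette_threshold < 1.0:
            raise ValidationError("silhouette_threshold must be in [-1, 1)")
        for name in ("window_size", "ld_window", "ld_bin", "f4_block_size"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        if self.control_min_depth < 0:
            raise ValidationError("control_min_depth must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
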