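"""Pipeline configuration: every tunable threshold in one validated object.

Defaults are the study-design values: background retention floor, log base
2 intensities, raw test level 0.05, BH FDR 0.1 for the regulated call,
twofold-change and twofold-ratio selection thresholds, 100 bootstrap
resamples, class-significance alpha 0.05, small-class flag below 5 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # input paths (None -> stage skipped or simulated upstream)
    matrix: str | None = None
    samples: str | None = None
    annotation: str | None = None
    qpcr: str | None = None
    outdir: str = "pbarray_out"
    # thresholds
    background: float = 50.0
    log_base: float = 2.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    ratio_hi: float = 2.0
    ratio_lo: float = 0.5
    bootstrap_B: int = 100
    alpha: float = 0.05
    small_class_min: int = 5
    normalization_mode: str = "upper_quartile"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.background <= 0:
            raise ConfigError("background must be > 0")
        if self.log_base <= 1:
            raise ConfigError("log_base must be > 1")
        for name in ("p_threshold", "fdr_threshold", "alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1]")
        for hi, lo in (("fc_hi", "fc_lo"), ("ratio_hi", "ratio_lo")):
            h, l = getattr(self, hi), getattr(self, lo)
            if not (h > 1 > l > 0):
                raise ConfigError(f"{hi}/{lo} must satisfy hi > 1 > lo > 0")
        if self.bootstrap_B < 2:
            raise ConfigError("bootstrap_B must be >= 2")
        if self.small_class_min < 1:
            raise ConfigError("small_class_min must be >= 1")
        if self.normalization_mode not in ("upper_quartile", "quantile"):
            raise ConfigError(f"unknown normalization_mode {self.normalization_mode!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {unknown}")
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        return asdict(self)
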