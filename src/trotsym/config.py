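"""Pipeline configuration.

A flat key-value YAML file can override the defaults; command-line flags
override file values in turn. Defaults reproduce the study's fixed
constants: 100 Hz sampling, 6/3/3 mm repeatability thresholds, a 25-stride
target per condition, 5% significance and 95% confidence levels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml


@dataclass
class PipelineConfig:
    fs_hz: float = 100.0
    threshold_head_mm: float = 6.0
    threshold_withers_mm: float = 3.0
    threshold_pelvis_mm: float = 3.0
    stride_outlier_frac: float = 0.25
    min_strides_warn: int = 25
    seed: int = 0
    alpha: float = 0.05
    conf_level: float = 0.95
    stride_time_ms: float = 720.0
    strides_per_condition: int = 30

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.conf_level < 1:
            raise ValueError("alpha and conf_level must lie in (0, 1)")

    @classmethod
    def load(cls, path: Optional[Union[str, Path]] = None, **overrides):
        """Defaults, updated from a YAML file, updated from keyword flags."""
        values = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(data) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
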