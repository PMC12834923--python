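"""Pipeline configuration: one YAML file, display-geometry defaults.

Defaults encode the study's acquisition setup — 50 px AOI margin, 50 px
coverage cell and buffer, strictly-greater-than-0.5 validity threshold,
60 Hz sampling, 0.233 mm pixel pitch viewed from 60 cm on a 2560 x 1440
display.  Operations take their parameters from here; no constant is
hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # paths
    dataset_dir: str = "dataset"
    output_dir: str = "results"
    # metric parameters
    aoi_margin_px: float = 50.0
    coverage_cell_px: int = 50
    coverage_buffer_px: float = 50.0
    validity_threshold: float = 0.5
    # acquisition / display geometry
    sampling_rate_hz: float = 60.0
    pixel_pitch_mm: float = 0.233
    viewing_distance_cm: float = 60.0
    image_width: int = 2560
    image_height: int = 1440
    # generator
    generator: str = "paper_defaults"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.validity_threshold < 0 or self.validity_threshold >= 1:
            raise ConfigError("validity_threshold must be in [0, 1)")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be > 0")
        if min(self.aoi_margin_px, self.coverage_buffer_px) < 0 or self.coverage_cell_px <= 0:
            raise ConfigError("metric parameters must be non-negative (cell > 0)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
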