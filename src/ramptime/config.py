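"""Pipeline configuration with the published analysis constants as defaults."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Analysis constants; every override from a file or CLI is logged.

    Defaults follow the published procedure: 15-ms Gaussian kernel, fit
    window from 300 ms before the cue (400 is the documented alternative),
    visual-transient exclusion 50-250 ms post-cue, 40-ms persistence at
    p < 0.01 for divergence, p < 0.01 duration selectivity, p < 0.05
    task-related screening, 1000 bootstrap resamples.
    """

    kernel_sigma_ms: float = 15.0
    fit_window_precue_ms: float = 300.0
    exclusion_ms: tuple[float, float] = (50.0, 250.0)
    persistence_ms: int = 40
    alpha_divergence: float = 0.01
    alpha_selectivity: float = 0.01
    alpha_task: float = 0.05
    bootstrap_B: int = 1000
    seed: int = 0
    rm_anova_sphericity_correction: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            default = getattr(cfg, key)
            if key == "exclusion_ms":
                value = tuple(float(v) for v in value)
            if value != default:
                logger.info("config override: %s = %r (default %r)", key, value, default)
            setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclusion_ms"] = list(self.exclusion_ms)
        return d
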