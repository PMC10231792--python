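"""Pipeline configuration: YAML-backed, hashable, flag-overridable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Settings shared across pipeline commands.

    ``alpha`` is the trajectory-contrast significance threshold (the screen's
    5e-5); ``padj_threshold`` the proteomics BH cut-off; imaging settings
    carry the 4 um vacuole diameter rule.
    """

    alpha: float = 5e-5
    n_interior_knots: int = 3
    spline_degree: int = 3
    crossing_rule: str = "consecutive"
    engine: str = "ols"
    de_path: str = "nb"  # nb | gaussian
    padj_threshold: float = 0.05
    pixel_size_um: float = 0.5
    min_diameter_um: float = 4.0
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.padj_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.engine not in ("ols", "random_intercept"):
            raise ValueError("engine must be 'ols' or 'random_intercept'")
        if self.de_path not in ("nb", "gaussian"):
            raise ValueError("de_path must be 'nb' or 'gaussian'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
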