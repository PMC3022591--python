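"""Run configuration: one serializable object holding every tunable default.

Round-trips losslessly through YAML; unknown keys are rejected so a typo in
a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    # spectra preprocessing
    grid_step: float = 0.5
    max_shift: float = 2.0
    snr_threshold: float = 5.0
    min_separation: float = 4.0
    baseline_window: float = 50.0
    noise_floor_snr: float = 3.0
    # normalization
    normalize: str = "control-deciles"   # or "none"
    # selection
    p_grid_min: float = 0.001
    p_grid_max: float = 0.1
    p_grid_points: int = 15
    intensity_grid_max: float = 500.0
    intensity_grid_step: float = 50.0
    cv_folds: int = 10
    # classifier
    C: float = 1.0
    # clinical rules
    max_depth: int = 4
    min_leaf: int = 5

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
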