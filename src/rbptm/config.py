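"""Analysis configuration.

Houses the handful of tunable parameters the analyses share: the
crosslink window width (21 residues), the mutation proximity radius
(10 residues), the conservation background sample size (100 positions
per protein), the eCLIP peak-overlap fraction (0.5), the high-conservation
threshold (0.9) and the significance level (0.05).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    window_size: int = 21
    proximity_k: int = 10
    background_n: int = 100
    overlap_fraction: float = 0.5
    high_conservation_threshold: float = 0.9
    alpha: float = 0.05
    seed: int = 0

    def validate(self):
        """Check every invariant; raise ValidationError listing all
        violations at once."""
        problems = []
        if self.window_size < 1 or self.window_size % 2 == 0:
            problems.append(f"window_size must be an odd positive integer, got {self.window_size}")
        if self.proximity_k < 0:
            problems.append(f"proximity_k must be >= 0, got {self.proximity_k}")
        if self.background_n < 1:
            problems.append(f"background_n must be >= 1, got {self.background_n}")
        if not (0.0 < self.overlap_fraction <= 1.0):
            problems.append(f"overlap_fraction must be in (0, 1], got {self.overlap_fraction}")
        if not (0.0 < self.alpha < 1.0):
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if problems:
            raise ValidationError(problems)
        return self

    @property
    def half_window(self):
        return (self.window_size - 1) // 2

    def to_dict(self):
        return dataclasses.asdict(self)

    def dump(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def validate_config(path):
    """Load a YAML/JSON config file, fill defaults, and check invariants.

    Unknown keys are rejected so typos never silently fall back to a
    default. An empty file yields the full default configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError([f"config root must be a mapping, got {type(data).__name__}"])
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    problems = [f"unknown config key: {k!r}" for k in data if k not in known]
    if problems:
        raise ValidationError(problems)
    cfg = AnalysisConfig(**data)
    return cfg.validate()


def config_to_json(cfg):
    return json.dumps(cfg.to_dict(), sort_keys=True)
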