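"""Pipeline configuration: every tunable of every stage in one mapping.

Round-trips losslessly through YAML; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ArgumentError


@dataclass
class PipelineConfig:
    # protocol / synthetic generator
    n_subjects: int = 2
    n_days: int = 5
    n_channels: int = 3
    n_synergies_true: int = 2
    n_cycles: int = 30
    samples_per_cycle: int = 200
    noise_sigma: float = 0.05
    sampling_rate: float = 50.0
    group_split: float = 0.0       # fraction of high-amplitude subjects
    amplitude_ratio: float = 1.5

    # preprocessing
    envelope_input: bool = True    # synthetic data is already envelope-level
    band_low: float = 20.0
    band_high: float = 450.0
    env_cutoff: float = 4.0
    normalize: str = "max"

    # decomposition
    method: str = "mcr_als"
    r: int | str = "auto"          # "auto" -> VAF-based order selection
    alpha: float = 0.03
    q_tol: float = 0.01            # percent
    max_iter: int = 1000
    vaf_threshold: float = 0.80

    # kinematics
    angle_cutoff: float = 2.0

    # regression
    n_layers: int = 5
    hidden_units: int = 48
    dropout: float = 0.3
    window_length: int = 200
    stride: int = 50
    epochs: int = 40
    learning_rate: float = 1e-3
    batch_size: int = 64

    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ArgumentError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**mapping)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ArgumentError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path):
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
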