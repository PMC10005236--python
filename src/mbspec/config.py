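"""Pipeline configuration: one flat, strictly-validated key set.

A single YAML file (or flag overrides) drives every stage; unknown keys
are rejected before any computation so that typos cannot silently fall
back to defaults.  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .synth import DEFAULT_COHORT, NoiseModel


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort simulation
    n_control: int = DEFAULT_COHORT["control"]
    n_classic: int = DEFAULT_COHORT["classic"]
    n_desmoplastic: int = DEFAULT_COHORT["desmoplastic"]
    n_anaplastic: int = DEFAULT_COHORT["anaplastic"]
    replicates: int = 3
    additive_sd: float = 0.004
    amplitude_jitter_cv: float = 0.05
    center_jitter_sd: float = 0.2
    inject_signature: bool = True
    signature_magnitude: float = 5.0
    # preprocessing
    n_baseline_points: int = 64
    sg_window: int = 9
    sg_polyorder: int = 3
    sg_window_d1: int = 7
    sg_polyorder_d1: int = 2
    # analysis
    k_threshold: float = 2.0
    match_tolerance: float = 4.0
    n_components: int = 2
    cut_clusters: int = 3

    def counts(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "classic": self.n_classic,
            "desmoplastic": self.n_desmoplastic,
            "anaplastic": self.n_anaplastic,
        }

    def noise(self) -> NoiseModel:
        return NoiseModel(
            additive_sd=self.additive_sd,
            amplitude_jitter_cv=self.amplitude_jitter_cv,
            center_jitter_sd=self.center_jitter_sd,
            seed=self.seed,
        )

    def preprocess(self) -> PreprocessConfig:
        return PreprocessConfig(
            n_baseline_points=self.n_baseline_points,
            sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder,
            sg_window_d1=self.sg_window_d1,
            sg_polyorder_d1=self.sg_polyorder_d1,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
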