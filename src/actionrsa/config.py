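"""Serializable pipeline configuration.

A single human-editable YAML document drives the end-to-end synthetic
pipeline. Every stochastic stage has an explicit seed; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .design import DesignConfig

__all__ = ["Seeds", "PipelineConfig"]


def _from_mapping(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class Seeds:
    ground_truth: int = 11
    surface: int = 12
    arrangement: int = 13
    design: int = 14
    patterns: int = 15
    images: int = 16
    permutation: int = 17
    clustering: int = 18

    def offset(self, delta: int) -> "Seeds":
        return Seeds(**{f.name: getattr(self, f.name) + delta
                        for f in fields(self)})


@dataclass(frozen=True)
class PipelineConfig:
    # planted structure
    n_items: int = 28
    n_clusters: int = 6
    cluster_spread: float = 5.0
    within_spread: float = 0.6
    latent_dim: int = 2
    # cohort
    n_subjects: int = 8
    arranger_noise_sd: float = 0.05
    arrangement_trials: int = 12
    # surface / searchlight
    mesh_subdivisions: int = 2
    region_size: int = 40
    searchlight_features: int = 30
    pattern_noise_sd: float = 0.3
    n_runs: int = 4
    # inference
    n_perm: int = 500
    initial_p: float = 0.001
    # characterization
    k_range: tuple[int, int] = (2, 10)
    kmeans_restarts: int = 100
    # design of the event sequences written alongside
    design: DesignConfig = field(default_factory=DesignConfig)
    seeds: Seeds = field(default_factory=Seeds)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "design" in data:
            data["design"] = _from_mapping(DesignConfig, data["design"])
        if "seeds" in data:
            data["seeds"] = _from_mapping(Seeds, data["seeds"])
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return _from_mapping(cls, data)
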