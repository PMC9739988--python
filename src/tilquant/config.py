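"""Pipeline configuration: nested sections mirroring each stage's parameters.

Defaults reproduce the standard analysis settings (0.5 µm/px working
resolution, the watershed detection parameter list, 25/50 µm feature
smoothing radii, an 8-unit MLP trained for up to 1000 iterations, a 10%
minimum group fraction for the cut-point scan and Efron tie handling).
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import ClassifierConfig
from .segmentation import DetectionParams

__all__ = ["PipelineConfig", "StainConfig", "FeatureConfig", "CutpointConfig",
           "SurvivalConfig", "TILsConfig"]

CONFIG_VERSION = 1


@dataclass(frozen=True)
class StainConfig:
    od_min: float = 0.15
    angle_percentile: float = 1.0
    background_intensity: float | None = None  # None: 99.9th percentile


@dataclass(frozen=True)
class FeatureConfig:
    smoothing_radii_um: tuple[float, ...] = (25.0, 50.0)


@dataclass(frozen=True)
class TILsConfig:
    include_ignore_in_total: bool = False


@dataclass(frozen=True)
class CutpointConfig:
    variable: str = "eTILs_pct"
    min_group_fraction: float = 0.1
    correction: str = "miller-siegmund"


@dataclass(frozen=True)
class SurvivalConfig:
    ties: str = "efron"
    etils_threshold: float = 13.2


@dataclass(frozen=True)
class PipelineConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    stain: StainConfig = field(default_factory=StainConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    tils: TILsConfig = field(default_factory=TILsConfig)
    cutpoint: CutpointConfig = field(default_factory=CutpointConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return convert(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "stain": StainConfig,
            "detection": DetectionParams,
            "features": FeatureConfig,
            "classifier": ClassifierConfig,
            "tils": TILsConfig,
            "cutpoint": CutpointConfig,
            "survival": SurvivalConfig,
        }
        kwargs = {}
        for key in ("version", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        for name, typ in sections.items():
            if name not in d:
                continue
            sub = d.pop(name)
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[name] = typ(**sub)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
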