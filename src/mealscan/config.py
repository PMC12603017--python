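"""Pipeline configuration: typed parameter blocks, strict YAML loading,
and an effective-config hash echoed into every report.

All randomized stages derive their seeds from one global seed via fixed
per-stage offsets, so a whole run is reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .association import FusionWeights
from .change_volume import ChangeParams
from .geometry import ParameterError
from .segmentation import SegmentationParams

SEED_OFFSETS = {
    "segmentation": 11,
    "registration": 23,
    "change": 37,
    "simulate": 53,
}


@dataclass
class RegistrationConfig:
    voxel: float = 0.003
    min_global_fitness: float = 0.3


@dataclass
class AssociationConfig:
    weights: FusionWeights = field(default_factory=FusionWeights)
    min_score: float = 0.3


@dataclass
class NutritionConfig:
    table_csv: Optional[str] = None  # None -> bundled demo table


@dataclass
class SimulateConfig:
    table_depth: float = 0.5
    noise_sigma: float = 0.001
    plate_radius: float = 0.09


@dataclass
class PipelineConfig:
    seed: int = 0
    verbosity: int = 0
    crop_margin: float = 0.02  # m added to plate radius when cropping
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    change: ChangeParams = field(default_factory=ChangeParams)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    nutrition: NutritionConfig = field(default_factory=NutritionConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def __post_init__(self) -> None:
        self.segmentation.seed = self.seed + SEED_OFFSETS["segmentation"]
        self.change.seed = self.seed + SEED_OFFSETS["change"]

    def to_dict(self) -> dict:
        return _asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data or {})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    return obj


def _build(cls, data: dict):
    """Instantiate a dataclass from a dict, rejecting unknown keys and
    recursing into nested dataclass blocks."""
    if not isinstance(data, dict):
        raise ParameterError(f"expected a mapping for {cls.__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    # recurse for nested dataclass fields given as dicts
    instance = cls()
    for name, value in data.items():
        current = getattr(instance, name)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            setattr(instance, name, _build(type(current), value))
        else:
            setattr(instance, name, value)
    if isinstance(instance, PipelineConfig):
        instance.__post_init__()
    return instance
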