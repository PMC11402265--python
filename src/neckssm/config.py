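"""Validated pipeline configuration (YAML-backed).

Every stage reads its settings from one :class:`PipelineConfig`; unknown
keys anywhere in the document are rejected so silent typos cannot change
an analysis.  The configuration hash in the run manifest is the SHA-256 of
the canonical JSON form.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from neckssm.errors import InvalidParameterError

__all__ = ["PipelineConfig", "CohortConfig", "ParametrizationConfig", "SSMConfig", "StatsConfig"]


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidParameterError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
            value = _from_dict(_NESTED[f.name], value or {})
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class CohortConfig:
    n_cases: int = 63
    n_controls: int = 63
    geometry: str = "mesh"  # mesh | analytic
    n_angular: int = 96
    axial_spacing_mm: float = 1.0
    surface_noise_sd_mm: float = 0.2
    case_overrides: dict = field(default_factory=dict)
    control_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.geometry not in ("mesh", "analytic"):
            raise InvalidParameterError("cohort.geometry must be 'mesh' or 'analytic'")
        if self.n_cases < 2 or self.n_controls < 2:
            raise InvalidParameterError("need >= 2 subjects per group")


@dataclass
class ParametrizationConfig:
    n_levels: int = 10
    n_angles: int = 360
    step_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.n_levels < 2 or self.n_angles < 8 or self.step_mm <= 0:
            raise InvalidParameterError("invalid parametrization settings")


@dataclass
class SSMConfig:
    retention_threshold: float = 0.98
    compute_generalization: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.retention_threshold <= 1):
            raise InvalidParameterError("retention_threshold must be in (0, 1]")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    probability_cutoff: float = 0.5
    category_coding: str = "ordinal"  # ordinal | dummy
    exact_test_budget: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.probability_cutoff < 1):
            raise InvalidParameterError("alpha and probability_cutoff must be in (0, 1)")
        if self.category_coding not in ("ordinal", "dummy"):
            raise InvalidParameterError("category_coding must be 'ordinal' or 'dummy'")


_NESTED = {
    "cohort": CohortConfig,
    "parametrization": ParametrizationConfig,
    "ssm": SSMConfig,
    "stats": StatsConfig,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    parametrization: ParametrizationConfig = field(default_factory=ParametrizationConfig)
    ssm: SSMConfig = field(default_factory=SSMConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
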