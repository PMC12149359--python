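"""Run configuration: one serializable structure covering every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .contour import SnakeParams
from .phantom import DeformationModel, ImagingConfig, PhantomGeometry
from .piv import PivConfig, RoiSpec
from .protocol import MotionProtocol

__all__ = ["RunConfig", "load_config", "config_hash"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisParams:
    piv_t_start: float = 10.0
    piv_t_end: float = 22.0
    modulus_window: tuple[float, float] = (0.025, 0.05)
    deformation_width_fraction: float = 0.1


@dataclass(frozen=True)
class RunConfig:
    protocol: MotionProtocol = field(default_factory=MotionProtocol)
    model: DeformationModel = field(default_factory=DeformationModel)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    snake: SnakeParams = field(default_factory=SnakeParams)
    roi: RoiSpec = field(default_factory=RoiSpec)
    piv: PivConfig = field(default_factory=PivConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    density: float = 6.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))


_SECTIONS = {
    "protocol": MotionProtocol,
    "model": DeformationModel,
    "imaging": ImagingConfig,
    "geometry": PhantomGeometry,
    "snake": SnakeParams,
    "roi": RoiSpec,
    "piv": PivConfig,
    "analysis": AnalysisParams,
}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{section}'")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML run config; missing sections/keys fall back to defaults."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data = loaded
    if overrides:
        data = {**data, **overrides}

    kwargs = {}
    for section, cls in _SECTIONS.items():
        sub = data.pop(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        kwargs[section] = _build_section(cls, sub, section)
    for scalar in ("density", "seed"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigError(f"unknown top-level key(s): {sorted(data)}")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_plain(config.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
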