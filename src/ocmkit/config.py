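"""Run configuration: a strict, YAML-round-trippable bundle of settings."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cycle import CompressionCycleSpec
from .errors import ConfigError
from .segmentation import SegmentationParams

__all__ = ["KineticsOptions", "RunConfig"]


@dataclass(frozen=True)
class KineticsOptions:
    """Analysis switches: display smoothing and fragment accounting."""

    smooth: bool = False
    smooth_window: int = 3


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    kwargs = dict(section)
    if cls is SegmentationParams and isinstance(kwargs.get("threshold"), str):
        raise ConfigError("segmentation.threshold must be an integer or null")
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one analysis run."""

    cycle: CompressionCycleSpec = field(default_factory=CompressionCycleSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    kinetics: KineticsOptions = field(default_factory=KineticsOptions)
    compendia: tuple[str, ...] = ("EuPh", "USP")
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "cycle": CompressionCycleSpec,
        "segmentation": SegmentationParams,
        "kinetics": KineticsOptions,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in data.items():
            if key in cls._SECTIONS:
                if not isinstance(value, dict):
                    raise ConfigError(f"section '{key}' must be a mapping")
                kwargs[key] = _build(cls._SECTIONS[key], value, key)
            elif key == "compendia":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["compendia"] = list(self.compendia)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
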