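"""Run configuration: YAML-compatible key-value file with strict keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Tool-wide defaults; CLI flags override individual entries."""

    materials_registry: str | None = None  # path; None = packaged registry
    database: str | None = None
    fit_band: tuple[float, float] = (450.0, 700.0)
    refine: bool = False
    correlation_floor: float = 0.8
    band: tuple[float, float] = (450.0, 700.0)
    sampling: float = 0.6
    lsf_fwhm: float = 0.6
    noise_sd: float = 0.01
    grid_offset_jitter: float = 0.15
    seed: int | None = None
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_band"] = list(self.fit_band)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        kwargs = dict(data)
        for key in ("fit_band", "band"):
            if key in kwargs and kwargs[key] is not None:
                seq = kwargs[key]
                if len(seq) != 2:
                    raise ConfigError(f"'{key}' must be [lo, hi], got {seq}")
                kwargs[key] = (float(seq[0]), float(seq[1]))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc is None:
            return cls()
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a key-value mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
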