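"""Run configuration: composite of the stage configs, YAML round-trip.

Unknown keys fail fast — silent default fallback on a typo has caused real
reproducibility bugs.  Defaults are the published constants: stability
thresholds -2.5 / -3.7 / -4.6 kcal/mol, coax joins restricted to k <= 1
(distance <= 2), internal-loop bounds 11 per side with asymmetry <= 4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .candidates import FinderConfig
from .dp import DPConfig
from .energy import EnergyConfig
from .errors import InputError


@dataclass
class RunConfig:
    """All tunables of one prediction run."""

    energy: EnergyConfig = field(default_factory=EnergyConfig)
    finder: FinderConfig = field(default_factory=FinderConfig)
    dp: DPConfig = field(default_factory=DPConfig)
    out_prefix: str = "coaxfold"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "energy": dataclasses.asdict(self.energy),
            "finder": dataclasses.asdict(self.finder),
            "dp": dataclasses.asdict(self.dp),
            "out_prefix": self.out_prefix,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _build(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise InputError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise InputError(f"bad value in {where}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    top = {"energy", "finder", "dp", "out_prefix", "log_level", "seed"}
    unknown = set(data) - top
    if unknown:
        raise InputError(f"unknown top-level key(s): {sorted(unknown)}")
    return RunConfig(
        energy=_build(EnergyConfig, data.get("energy", {}) or {}, "energy"),
        finder=_build(FinderConfig, data.get("finder", {}) or {}, "finder"),
        dp=_build(DPConfig, data.get("dp", {}) or {}, "dp"),
        out_prefix=data.get("out_prefix", "coaxfold"),
        log_level=data.get("log_level", "INFO"),
        seed=data.get("seed", 0),
    )


def load_config(path: str | None = None) -> RunConfig:
    """RunConfig from a YAML file, or defaults when no path is given."""
    if path is None:
        return RunConfig()
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise InputError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise InputError(f"config file {path} must hold a mapping")
    return config_from_dict(data)
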