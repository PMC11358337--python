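"""Configuration loading, validation and the resolved-config echo.

Config files are TOML (YAML accepted) with sections ``[environment]``,
``[microclimate]``, ``[chemistry]``, ``[kinetics]``, ``[initial]`` and
``[run]``.  Every key is optional — an empty file yields the full default
configuration — but unknown keys and invariant violations are errors.
Acid dissociation constants may be given as molar pKa values
(``pKa_CO2``/``pKa_OA``), converted internally to mol m^-3.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chemistry import ChemistryParams
from .environment import SeasonPreset, get_preset
from .metabolism import KineticParams
from .microclimate import MicroclimateParams
from .model import InitialState, ModelParams


@dataclass(frozen=True)
class RunConfig:
    """Integration horizon and output grid."""

    n_days: int = 60
    grid_h: float = 0.1        # output grid step [h]
    rtol: float = 1e-6
    method: str = "LSODA"
    periodic_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.grid_h <= 0:
            raise ValueError("grid_h must be positive")


@dataclass(frozen=True)
class EnvironmentConfig:
    """Forcing source: a seasonal preset or a measured-profile CSV."""

    preset: str = "summer"
    forcing_csv: str | None = None   # overrides the preset when given
    resolution_h: float = 0.25
    overrides: dict = field(default_factory=dict)   # SeasonPreset fields

    def season_preset(self) -> SeasonPreset:
        return get_preset(self.preset, **self.overrides)


@dataclass
class Config:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    microclimate: MicroclimateParams = field(default_factory=MicroclimateParams)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    initial: InitialState = field(default_factory=InitialState)
    run: RunConfig = field(default_factory=RunConfig)

    def model_params(self) -> ModelParams:
        return ModelParams(kinetics=self.kinetics, chemistry=self.chemistry,
                           microclimate=self.microclimate)


_SECTIONS = {
    "environment": EnvironmentConfig,
    "microclimate": MicroclimateParams,
    "chemistry": ChemistryParams,
    "kinetics": KineticParams,
    "initial": InitialState,
    "run": RunConfig,
}

# user-facing unit conveniences: (section, key) -> (target key, converter)
_ALIASES = {
    ("microclimate", "lambda_um"): ("lambda_m", lambda v: v * 1e-6),
    ("microclimate", "delta_mm"): ("delta_m", lambda v: v * 1e-3),
    ("chemistry", "pKa_CO2"): ("Ka_CO2", lambda v: 1e3 * 10.0 ** (-v)),
    ("chemistry", "pKa_OA"): ("Ka_OA", lambda v: 1e3 * 10.0 ** (-v)),
}


def _build_section(name: str, raw: dict):
    cls = _SECTIONS[name]
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    unknown = []
    for key, value in raw.items():
        if (name, key) in _ALIASES:
            target, conv = _ALIASES[(name, key)]
            kwargs[target] = conv(value)
        elif key in fields:
            kwargs[key] = value
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {unknown}")
    return cls(**kwargs)


def config_from_dict(data: dict) -> Config:
    unknown = [k for k in data if k not in _SECTIONS]
    if unknown:
        raise ValueError(f"unknown config sections: {unknown}")
    sections = {name: _build_section(name, data.get(name, {}) or {})
                for name in _SECTIONS}
    return Config(**sections)


def load_config(path: str | Path | None) -> Config:
    """Load and validate a TOML or YAML config; ``None`` gives defaults."""
    if path is None:
        return Config()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_bytes()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    else:
        data = tomllib.loads(text.decode())
    if not isinstance(data, dict):
        raise ValueError("config root must be a table/mapping")
    return config_from_dict(data)


def config_to_dict(cfg: Config) -> dict:
    out = {}
    for name in _SECTIONS:
        section = getattr(cfg, name)
        out[name] = dataclasses.asdict(section)
    return out


def write_resolved_config(cfg: Config, path: str | Path) -> None:
    """Echo the fully-resolved configuration; re-loading it reproduces cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
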