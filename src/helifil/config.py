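"""Run configuration: lattice constants, EM-derived filament geometry,
electrostatic model parameters and the global seed.

Geometry values are stored in Angstrom internally; the EM block of a YAML
or TOML config file is written in nm (the scale the microscopy literature
uses) and converted on load.

The default EM ranges are the package's calibration of the filament
geometry: the mean (40.4 nm diameter, 19.3 nm coil separation) gives a
21-dimer registry and the 193 A final stretch target, and the corners of
the range span filament heights of 180-240 nm for the 195-dimer model.
Override them from a config file when measured ranges are available.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .lattice import LatticeSpec

__all__ = [
    "EMParams",
    "RunConfig",
    "load_config",
    "default_config",
    "protocol_from_obj",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EMParams:
    """Filament geometry from negative-stain EM, Angstrom."""

    diameter_mean: float = 404.0
    diameter_min: float = 390.0
    diameter_max: float = 412.0
    coil_separation_mean: float = 193.0
    coil_separation_min: float = 186.0
    coil_separation_max: float = 239.0

    def __post_init__(self) -> None:
        for lo, mid, hi in (
            (self.diameter_min, self.diameter_mean, self.diameter_max),
            (
                self.coil_separation_min,
                self.coil_separation_mean,
                self.coil_separation_max,
            ),
        ):
            if not (0 < lo <= mid <= hi):
                raise ConfigError("EM ranges must be ordered and positive")

    @property
    def mean(self) -> dict:
        return {
            "diameter": self.diameter_mean,
            "coil_separation": self.coil_separation_mean,
        }


@dataclass(frozen=True)
class RunConfig:
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    em: EMParams = field(default_factory=EMParams)
    es: dict = field(default_factory=dict)  # ESModel overrides
    protocol: tuple = ()  # optimization stage dicts
    grid_increment: float = 1.0  # A (0.1 nm)
    seed: int = 0
    out_dir: str = "."

    def es_model(self):
        from .energy import ESModel

        return ESModel(**self.es)

    def protocol_spec(self):
        """ProtocolSpec from the config's stage list (canonical
        SD/NVT/quasi-Newton protocol when none is configured)."""
        from .restraints import sd_nvt_qn

        if not self.protocol:
            return sd_nvt_qn()
        return protocol_from_obj(self.protocol)


def protocol_from_obj(stages) -> "ProtocolSpec":
    """Build a ProtocolSpec from a list of stage mappings, e.g.

    - {minimize: {max_steps: 2000, tol: 0.001, method: sd}}
    - {dynamics: {n_steps: 1000, temperature: 100, dt: 0.002}}
    """
    from .restraints import DynamicsStage, MinimizeStage, ProtocolSpec

    out = []
    for stage in stages:
        if len(stage) != 1:
            raise ConfigError(f"ambiguous protocol stage {stage!r}")
        kind, kwargs = next(iter(stage.items()))
        kwargs = dict(kwargs or {})
        if kind == "minimize":
            out.append(MinimizeStage(**kwargs))
        elif kind == "dynamics":
            out.append(DynamicsStage(**kwargs))
        else:
            raise ConfigError(f"unknown protocol stage kind {kind!r}")
    return ProtocolSpec(stages=tuple(out))


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load a YAML config; missing blocks keep their defaults.

    Recognized blocks: ``lattice`` (A), ``em`` (nm: diameter_mean_nm,
    coil_separation_min_nm, ...), ``grid_increment_nm``, ``seed``,
    ``out_dir``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = default_config()
    if "lattice" in raw:
        cfg = replace(cfg, lattice=LatticeSpec(**raw["lattice"]))
    if "em" in raw:
        em_kwargs = {}
        for key, value in raw["em"].items():
            if not key.endswith("_nm"):
                raise ConfigError(
                    f"em block keys must be in nm (got {key!r})"
                )
            em_kwargs[key[:-3]] = float(value) * 10.0
        cfg = replace(cfg, em=EMParams(**em_kwargs))
    if "es" in raw:
        cfg = replace(cfg, es=dict(raw["es"]))
        cfg.es_model()  # validate eagerly
    if "protocol" in raw:
        cfg = replace(cfg, protocol=tuple(raw["protocol"]))
        cfg.protocol_spec()  # validate eagerly
    if "grid_increment_nm" in raw:
        cfg = replace(cfg, grid_increment=float(raw["grid_increment_nm"]) * 10)
    if "seed" in raw:
        cfg = replace(cfg, seed=int(raw["seed"]))
    if "out_dir" in raw:
        cfg = replace(cfg, out_dir=str(raw["out_dir"]))
    return cfg
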