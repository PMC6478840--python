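"""Run configuration: YAML-backed, validated before any computation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from . import __version__
from .chemotaxis import ChemotaxisParameters
from .errors import InvalidConfigurationError
from .geometry import (ConcentrationField, MazeGeometry,
                       build_concentration_field, build_maze_geometry)
from .population import PopulationHyperparameters

__all__ = ["RunConfig", "load_config"]

_KNOWN_BLOCKS = {"geometry", "gradient", "chemotaxis", "population",
                 "simulation", "output_dir"}

_SIM_DEFAULTS = {"dx_um": 10.0, "dt_s": 1.0, "t_end_min": 160.0,
                 "record_min": [40.0, 80.0, 120.0, 160.0],
                 "seed": 0, "n_agents": 10000, "agent_dt_s": 0.5}

_REGIME_SOURCES = {"linear": 5.0, "log": 500.0}


@dataclass
class RunConfig:
    """Validated configuration bundle; defaults reproduce the reference
    device and population."""

    geometry: dict = field(default_factory=dict)
    gradient: dict = field(default_factory=dict)
    chemotaxis: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    output_dir: str = "tmaze_output"

    def __post_init__(self):
        sim = dict(_SIM_DEFAULTS)
        sim.update(self.simulation)
        self.simulation = sim
        for key, val in (("dx_um", sim["dx_um"]), ("dt_s", sim["dt_s"]),
                         ("t_end_min", sim["t_end_min"])):
            if val <= 0:
                raise InvalidConfigurationError(f"simulation.{key} must be positive")
        # constructing the objects is the schema validation
        self.build_geometry()
        self.build_field()
        self.build_params()
        self.build_hyper()

    def build_geometry(self) -> MazeGeometry:
        return build_maze_geometry(self.geometry)

    def build_field(self) -> ConcentrationField:
        grad = dict(self.gradient)
        regime = grad.pop("regime", "linear")
        if regime not in ("linear", "log", "full"):
            raise InvalidConfigurationError(f"unknown regime {regime!r}")
        source = grad.pop("source", _REGIME_SOURCES.get(regime, 5.0))
        sink = grad.pop("sink", 0.0)
        band = tuple(grad.pop("band", (0.094, 0.938)))
        if grad:
            raise InvalidConfigurationError(f"unknown gradient keys {sorted(grad)}")
        return build_concentration_field(self.build_geometry(), source, sink,
                                         regime=regime, band=band)

    def build_params(self) -> ChemotaxisParameters:
        return ChemotaxisParameters(**self.chemotaxis)

    def build_hyper(self) -> PopulationHyperparameters:
        return PopulationHyperparameters(**self.population)

    def provenance(self) -> dict:
        blob = json.dumps({"geometry": self.geometry, "gradient": self.gradient,
                           "chemotaxis": self.chemotaxis,
                           "population": self.population,
                           "simulation": self.simulation}, sort_keys=True)
        return {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "seed": self.simulation["seed"],
                "package_version": __version__}


def load_config(path: str | None) -> RunConfig:
    """Load a YAML run configuration (``None`` → all defaults)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigurationError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise InvalidConfigurationError(f"unknown config blocks {sorted(unknown)}")
    return RunConfig(**raw)
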