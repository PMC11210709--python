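"""JSON configuration schema for the column model.

A config document fully describes a run: cell templates, populations
(explicit positions or the default grid builder), the connectivity
table, drives, integration settings and output options, plus an
optional optimization section.  Unknown keys are rejected; validation
reports every violation at once with its JSON path; parse → serialize →
parse is the identity.
"""

from __future__ import annotations

import json
from typing import Any, Dict, List, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cells import CellTemplate, build_template
from .drives import Drive
from .engine import SimulationSettings
from .network import ConnectionRule, Network, Population, default_network

SCHEMA_VERSION = 1


class ConfigValidationError(ValueError):
    """All schema violations, each with a JSON path."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BuilderConfig(_Strict):
    grid_shape: Tuple[int, int] = (10, 10)
    n_basket: int = Field(35, ge=1)


class PopulationConfig(_Strict):
    cell_class: str
    positions: List[Tuple[float, float, float]]


class RuleConfig(_Strict):
    src_class: str
    dst_class: str
    receptor: str
    target_site: str
    weight: float = Field(ge=0)
    delay: float = Field(gt=0)
    space_constant: Optional[float] = Field(None, gt=0)


class DriveConfig(_Strict):
    name: str
    kind: Literal["evoked", "rhythmic", "poisson", "tonic"]
    location: Literal["proximal", "distal"] = "proximal"
    mu: Optional[float] = None
    sigma: float = Field(0.0, ge=0)
    numspikes: int = Field(1, ge=1)
    burst_rate: Optional[float] = Field(None, gt=0)
    rate: Optional[float] = Field(None, ge=0)
    amplitudes: Dict[str, float] = Field(default_factory=dict)
    t_start: float = 0.0
    t_stop: Optional[float] = None
    weights: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    synaptic_delays: Dict[str, float] = Field(default_factory=dict)
    seed: Optional[int] = None
    target_distal_basket: bool = True


class NetworkConfig(_Strict):
    builder: Optional[BuilderConfig] = None
    populations: Optional[List[PopulationConfig]] = None
    connectivity: Optional[List[RuleConfig]] = None
    drives: List[DriveConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.builder is None) == (self.populations is None):
            raise ValueError("exactly one of builder or populations is required")
        return self


class SimulationConfig(_Strict):
    tstop: float = Field(gt=0)
    dt: float = Field(0.025, gt=0, le=0.1)
    n_trials: int = Field(1, ge=1)
    master_seed: int = 0
    record_voltages: bool = False


class OutputsConfig(_Strict):
    out_dir: str = "out"
    dipole_file: str = "dipole.txt"
    spikes_file: str = "spikes.txt"
    lfp_file: str = "lfp.txt"
    smoothing_window_ms: float = Field(0.0, ge=0)
    scaling: float = 1.0


class OptParamConfig(_Strict):
    drive: str
    fieldname: str
    bounds: Tuple[float, float]


class OptimizationConfig(_Strict):
    params: List[OptParamConfig]
    target_file: str
    budget: int = Field(100, ge=1)
    seed: int = 0
    windows: Dict[str, Tuple[float, float]] = Field(default_factory=dict)


class ConfigDocument(_Strict):
    schema_version: int = SCHEMA_VERSION
    templates: Optional[Dict[str, Any]] = None
    network: NetworkConfig
    simulation: SimulationConfig
    outputs: OutputsConfig = Field(default_factory=OutputsConfig)
    optimization: Optional[OptimizationConfig] = None

    @model_validator(mode="after")
    def _check_templates(self):
        if self.templates is not None:
            for cls, tpl in self.templates.items():
                try:
                    CellTemplate.from_dict(tpl)
                except Exception as err:
                    raise ValueError(f"templates.{cls}: {err}") from err
        return self


def _format_errors(err: ValidationError) -> List[str]:
    out = []
    for e in err.errors():
        path = ""
        for loc in e["loc"]:
            path = f"{path}[{loc}]" if isinstance(loc, int) else \
                (f"{path}.{loc}" if path else str(loc))
        out.append(f"{path}: {e['msg']}")
    return out


def parse_config(data: dict) -> ConfigDocument:
    try:
        doc = ConfigDocument.model_validate(data)
    except ValidationError as err:
        raise ConfigValidationError(_format_errors(err)) from err
    if doc.schema_version != SCHEMA_VERSION:
        raise ConfigValidationError(
            [f"schema_version: expected {SCHEMA_VERSION}, got {doc.schema_version}"])
    return doc


def load_config(path) -> ConfigDocument:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigValidationError([f"<file>: invalid JSON: {err}"]) from err
    return parse_config(data)


def save_config(path, doc: ConfigDocument) -> None:
    with open(path, "w") as fh:
        json.dump(doc.model_dump(mode="json"), fh, indent=1)
        fh.write("\n")


def network_from_config(doc: ConfigDocument) -> Network:
    """Instantiate the Network a config document describes."""
    templates = None
    if doc.templates is not None:
        templates = {cls: CellTemplate.from_dict(tpl)
                     for cls, tpl in doc.templates.items()}
    if doc.network.builder is not None:
        b = doc.network.builder
        net = default_network(grid_shape=tuple(b.grid_shape), n_basket=b.n_basket)
        if templates is not None:
            net.templates.update(templates)
        if doc.network.connectivity is not None:
            net.connectivity = []
            for rule in doc.network.connectivity:
                net.connect(ConnectionRule(**rule.model_dump()))
    else:
        pops = [Population(p.cell_class, [tuple(x) for x in p.positions])
                for p in doc.network.populations]
        rules = [ConnectionRule(**r.model_dump())
                 for r in (doc.network.connectivity or [])]
        net = Network(pops, connectivity=rules, templates=templates)
    for d in doc.network.drives:
        net._add_drive(Drive(**d.model_dump()))
    return net


def settings_from_config(doc: ConfigDocument) -> SimulationSettings:
    s = doc.simulation
    return SimulationSettings(tstop=s.tstop, dt=s.dt, n_trials=s.n_trials,
                              master_seed=s.master_seed,
                              record_voltages=s.record_voltages)


def config_from_network(net: Network, settings: SimulationSettings,
                        include_templates: bool = True) -> ConfigDocument:
    """Serialise a network + settings into an explicit config document.

    Together with :func:`network_from_config` this round-trips a network
    exactly (templates, positions, connectivity and drives included).
    """
    return ConfigDocument(
        schema_version=SCHEMA_VERSION,
        templates=({cls: tpl.to_dict() for cls, tpl in net.templates.items()}
                   if include_templates else None),
        network=NetworkConfig(
            populations=[PopulationConfig(cell_class=p.cell_class,
                                          positions=[tuple(x) for x in p.positions])
                         for p in net.populations],
            connectivity=[RuleConfig(**r.to_dict()) for r in net.connectivity],
            drives=[DriveConfig(**d.to_dict()) for d in net.drives],
        ),
        simulation=SimulationConfig(
            tstop=settings.tstop, dt=settings.dt, n_trials=settings.n_trials,
            master_seed=settings.master_seed,
            record_voltages=settings.record_voltages),
    )


def default_config(tstop: float = 100.0) -> ConfigDocument:
    """Config equivalent to the default column with no drives."""
    return ConfigDocument(
        schema_version=SCHEMA_VERSION,
        network=NetworkConfig(builder=BuilderConfig()),
        simulation=SimulationConfig(tstop=tstop),
    )
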