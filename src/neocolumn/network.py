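"""Network assembly: populations on a grid, connectivity, drives.

The canonical column holds, per layer (L2/3 and L5), a 10x10 grid of
pyramidal cells plus 35 interleaved basket interneurons.  Connectivity
is a flat table of class-to-class rules (receptor, target site, weight,
delay, optional Gaussian in-plane fall-off), fully editable.  Exogenous
drives attach to the network by name and target the proximal or distal
dendritic site groups layer-specifically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cells import (
    BASKET_CLASSES,
    CELL_CLASSES,
    PYRAMIDAL_CLASSES,
    RECEPTORS,
    CellTemplate,
    TemplateValidationError,
    balance_leak,
    build_template,
)
from .drives import Drive

GRID_SPACING = 100.0  # µm in-plane
LAYER_Z = {"L2": 1000.0, "L5": 0.0}  # soma depth of each layer, µm
VALID_SITES = ("proximal", "distal", "soma")


@dataclass
class Population:
    """All cells of one class, with their soma positions (µm)."""

    cell_class: str
    positions: List[Tuple[float, float, float]]

    @property
    def count(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if len(set(map(tuple, self.positions))) != len(self.positions):
            raise ValueError(f"{self.cell_class}: positions must be unique")


@dataclass
class ConnectionRule:
    """One class-to-class synaptic projection.

    ``space_constant`` (µm), when set, scales each pair's weight by
    exp(-d²/λ²) with d the in-plane (x, y) source-target distance;
    ``None`` means uniform all-to-all.
    """

    src_class: str
    dst_class: str
    receptor: str
    target_site: str
    weight: float  # µS (peak conductance)
    delay: float  # ms
    space_constant: Optional[float] = None

    def validate(self) -> None:
        if self.src_class not in CELL_CLASSES:
            raise ValueError(f"unknown src_class {self.src_class!r}")
        if self.dst_class not in CELL_CLASSES:
            raise ValueError(f"unknown dst_class {self.dst_class!r}")
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.target_site not in VALID_SITES:
            raise ValueError(f"unknown target_site {self.target_site!r}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.delay <= 0:
            raise ValueError("delay must be > 0")
        if self.space_constant is not None and self.space_constant <= 0:
            raise ValueError("space_constant must be > 0")

    def to_dict(self) -> dict:
        return {
            "src_class": self.src_class,
            "dst_class": self.dst_class,
            "receptor": self.receptor,
            "target_site": self.target_site,
            "weight": self.weight,
            "delay": self.delay,
            "space_constant": self.space_constant,
        }


class Network:
    """A column model: populations + connectivity + drives + templates."""

    def __init__(
        self,
        populations: Sequence[Population],
        connectivity: Optional[Sequence[ConnectionRule]] = None,
        templates: Optional[Dict[str, CellTemplate]] = None,
    ):
        self.populations: List[Population] = list(populations)
        self.connectivity: List[ConnectionRule] = []
        self.drives: List[Drive] = []
        if templates is None:
            templates = {p.cell_class: build_template(p.cell_class)
                         for p in self.populations}
        self.templates: Dict[str, CellTemplate] = templates
        for p in self.populations:
            p.validate()
        classes = [p.cell_class for p in self.populations]
        if len(set(classes)) != len(classes):
            raise ValueError("duplicate population cell_class")
        for rule in connectivity or []:
            self.connect(rule)

    # -- introspection -------------------------------------------------------

    @property
    def cell_classes(self) -> List[str]:
        return [p.cell_class for p in self.populations]

    def population(self, cell_class: str) -> Population:
        for p in self.populations:
            if p.cell_class == cell_class:
                return p
        raise KeyError(cell_class)

    @property
    def n_cells(self) -> int:
        return sum(p.count for p in self.populations)

    def gid_ranges(self) -> Dict[str, range]:
        """Contiguous global-id block per population, in population order."""
        out, start = {}, 0
        for p in self.populations:
            out[p.cell_class] = range(start, start + p.count)
            start += p.count
        return out

    def gid_to_class(self) -> Dict[int, str]:
        return {gid: cls for cls, rng in self.gid_ranges().items() for gid in rng}

    # -- connectivity --------------------------------------------------------

    def connect(self, rule: ConnectionRule) -> "Network":
        rule.validate()
        for cls in (rule.src_class, rule.dst_class):
            if cls not in self.cell_classes:
                raise ValueError(f"rule references absent population {cls!r}")
        dst_tpl = self.templates[rule.dst_class]
        if rule.target_site not in dst_tpl.synapse_sites:
            raise ValueError(
                f"{rule.dst_class} has no {rule.target_site!r} synapse site"
            )
        self.connectivity.append(rule)
        return self

    def pair_weights(self, rule: ConnectionRule) -> np.ndarray:
        """(n_src, n_dst) weight matrix in µS after spatial fall-off and
        autapse removal."""
        src = self.population(rule.src_class)
        dst = self.population(rule.dst_class)
        w = np.full((src.count, dst.count), rule.weight)
        if rule.space_constant is not None:
            sp = np.asarray(src.positions)[:, :2]
            dp = np.asarray(dst.positions)[:, :2]
            d2 = ((sp[:, None, :] - dp[None, :, :]) ** 2).sum(axis=2)
            w = w * np.exp(-d2 / rule.space_constant**2)
        if rule.src_class == rule.dst_class:
            np.fill_diagonal(w, 0.0)
        return w

    # -- cell modification ---------------------------------------------------

    def modify_cell(self, cell_class: str, patch: dict) -> "Network":
        """Apply a partial-template patch; invariants are re-validated and a
        violation is rejected naming the offending field.

        Recognised top-level keys: ``capacitance``, ``axial_resistivity``,
        ``v_rest``, ``geometry`` (comp -> {length, diameter, z_span}),
        ``mechanisms`` (comp -> kind -> {gbar, e_rev}), ``synapses``
        (receptor -> {tau_rise, tau_decay, e_rev}).
        """
        if cell_class not in self.templates:
            raise KeyError(cell_class)
        tpl = self.templates[cell_class].copy()
        allowed = {"capacitance", "axial_resistivity", "v_rest",
                   "geometry", "mechanisms", "synapses"}
        unknown = set(patch) - allowed
        if unknown:
            raise TemplateValidationError(f"unknown patch fields {sorted(unknown)}")
        explicit_leak_erev = set()
        for key in ("capacitance", "axial_resistivity", "v_rest"):
            if key in patch:
                setattr(tpl, key, patch[key])
        for comp, fields in patch.get("geometry", {}).items():
            geo = tpl.compartment(comp)
            for f, val in fields.items():
                if f not in ("length", "diameter", "z_span"):
                    raise TemplateValidationError(f"geometry.{comp}.{f}: unknown field")
                setattr(geo, f, val)
        for comp, kinds in patch.get("mechanisms", {}).items():
            mechs = tpl.mechanisms.get(comp)
            if mechs is None:
                raise TemplateValidationError(f"mechanisms.{comp}: unknown compartment")
            for kind, fields in kinds.items():
                target = [m for m in mechs if m.kind == kind]
                if not target:
                    raise TemplateValidationError(
                        f"mechanisms.{comp}.{kind}: mechanism not present")
                for f, val in fields.items():
                    if f not in ("gbar", "e_rev"):
                        raise TemplateValidationError(
                            f"mechanisms.{comp}.{kind}.{f}: unknown field")
                    setattr(target[0], f, val)
                    if kind == "leak" and f == "e_rev":
                        explicit_leak_erev.add(comp)
        for receptor, fields in patch.get("synapses", {}).items():
            if receptor not in tpl.synapses:
                raise TemplateValidationError(f"synapses.{receptor}: unknown receptor")
            spec = tpl.synapses[receptor]
            tr = fields.get("tau_rise", spec.tau_rise)
            td = fields.get("tau_decay", spec.tau_decay)
            if not (0 < tr < td):
                raise TemplateValidationError(
                    f"synapses.{receptor}.tau_rise: require 0 < tau_rise < tau_decay")
            spec.tau_rise, spec.tau_decay = tr, td
            if "e_rev" in fields:
                spec.e_rev = fields["e_rev"]
        if not explicit_leak_erev:
            balance_leak(tpl)
        tpl.validate()
        self.templates[cell_class] = tpl
        return self

    # -- drives --------------------------------------------------------------

    def _add_drive(self, drive: Drive) -> "Network":
        if any(d.name == drive.name for d in self.drives):
            raise ValueError(f"duplicate drive name {drive.name!r}")
        for cls in drive.targeted_classes():
            if cls not in self.cell_classes:
                raise ValueError(
                    f"drive {drive.name!r} targets absent population {cls!r}")
        for cls, site in self.drive_targets(drive):
            if site not in self.templates[cls].synapse_sites:
                raise ValueError(
                    f"drive {drive.name!r}: {cls} has no {site!r} site")
        self.drives.append(drive)
        return self

    def drive_targets(self, drive: Drive) -> List[Tuple[str, str]]:
        """(cell_class, site) pairs a drive attaches to.

        Proximal drives reach the proximal dendrites of pyramidal classes
        and the somata of basket classes; distal drives reach the distal
        apical tufts (plus L2 basket somata when enabled).
        """
        out = []
        for cls in drive.targeted_classes():
            if cls in PYRAMIDAL_CLASSES:
                out.append((cls, drive.location))
            elif drive.location == "proximal":
                out.append((cls, "soma"))
            elif drive.target_distal_basket and cls == "L2_basket":
                out.append((cls, "soma"))
        return out

    def add_evoked_drive(self, name: str, *, mu: float, sigma: float,
                         numspikes: int, location: str = "proximal",
                         weights_ampa: Optional[Dict[str, float]] = None,
                         weights_nmda: Optional[Dict[str, float]] = None,
                         synaptic_delays: Optional[Dict[str, float]] = None,
                         seed: Optional[int] = None) -> "Network":
        weights = {}
        if weights_ampa:
            weights["ampa"] = dict(weights_ampa)
        if weights_nmda:
            weights["nmda"] = dict(weights_nmda)
        return self._add_drive(Drive(
            name=name, kind="evoked", location=location, mu=mu, sigma=sigma,
            numspikes=numspikes, weights=weights,
            synaptic_delays=dict(synaptic_delays or {}), seed=seed))

    def add_rhythmic_drive(self, name: str, *, burst_rate: float,
                           sigma: float = 0.0, numspikes: int = 2,
                           t_start: float = 0.0, t_stop: float = None,
                           location: str = "proximal",
                           weights_ampa: Optional[Dict[str, float]] = None,
                           weights_nmda: Optional[Dict[str, float]] = None,
                           synaptic_delays: Optional[Dict[str, float]] = None,
                           seed: Optional[int] = None,
                           target_distal_basket: bool = True) -> "Network":
        weights = {}
        if weights_ampa:
            weights["ampa"] = dict(weights_ampa)
        if weights_nmda:
            weights["nmda"] = dict(weights_nmda)
        return self._add_drive(Drive(
            name=name, kind="rhythmic", location=location,
            burst_rate=burst_rate, sigma=sigma, numspikes=numspikes,
            t_start=t_start, t_stop=t_stop, weights=weights,
            synaptic_delays=dict(synaptic_delays or {}), seed=seed,
            target_distal_basket=target_distal_basket))

    def add_poisson_drive(self, name: str, *, rate: float,
                          t_start: float = 0.0, t_stop: float = None,
                          location: str = "proximal",
                          weights_ampa: Optional[Dict[str, float]] = None,
                          weights_nmda: Optional[Dict[str, float]] = None,
                          synaptic_delays: Optional[Dict[str, float]] = None,
                          seed: Optional[int] = None) -> "Network":
        weights = {}
        if weights_ampa:
            weights["ampa"] = dict(weights_ampa)
        if weights_nmda:
            weights["nmda"] = dict(weights_nmda)
        return self._add_drive(Drive(
            name=name, kind="poisson", rate=rate, location=location,
            t_start=t_start, t_stop=t_stop, weights=weights,
            synaptic_delays=dict(synaptic_delays or {}), seed=seed))

    def add_tonic_bias(self, name: str, *, amplitudes: Dict[str, float],
                       t_start: float = 0.0,
                       t_stop: Optional[float] = None) -> "Network":
        """Constant soma current injection (nA) per cell class."""
        return self._add_drive(Drive(
            name=name, kind="tonic", amplitudes=dict(amplitudes),
            t_start=t_start, t_stop=t_stop))

    def copy(self) -> "Network":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# default column builder
# ---------------------------------------------------------------------------


def _pyramidal_grid(n_side: int, z: float) -> List[Tuple[float, float, float]]:
    xs = np.arange(n_side) * GRID_SPACING
    return [(float(x), float(y), z) for x in xs for y in xs]


def _basket_grid(n_basket: int, extent: float, z: float
                 ) -> List[Tuple[float, float, float]]:
    """Interleave ``n_basket`` cells on a sparser grid covering the same
    in-plane extent, offset half a spacing from the pyramidal grid."""
    n_x = int(np.ceil(np.sqrt(n_basket)))
    n_y = int(np.ceil(n_basket / n_x))
    xs = np.linspace(0, extent, n_x) + GRID_SPACING / 2.0
    ys = np.linspace(0, extent, n_y) + GRID_SPACING / 2.0
    pos = [(float(x), float(y), z) for y in ys for x in xs]
    return pos[:n_basket]


_DEFAULT_RULES = [
    # src, dst, receptor, site, weight µS, delay ms, lambda µm
    # L2/3 recurrent excitation and its basket loop
    ("L2_pyramidal", "L2_pyramidal", "ampa", "proximal", 5e-4, 1.0, 300.0),
    ("L2_pyramidal", "L2_pyramidal", "nmda", "proximal", 5e-4, 1.0, 300.0),
    ("L2_pyramidal", "L2_basket", "ampa", "soma", 5e-4, 1.0, 300.0),
    ("L2_basket", "L2_pyramidal", "gabaa", "soma", 5e-2, 1.0, 500.0),
    ("L2_basket", "L2_pyramidal", "gabab", "soma", 5e-3, 1.0, 500.0),
    ("L2_basket", "L2_basket", "gabaa", "soma", 2e-3, 1.0, 500.0),
    # L5 recurrent excitation and its basket loop
    ("L5_pyramidal", "L5_pyramidal", "ampa", "proximal", 5e-4, 1.0, 300.0),
    ("L5_pyramidal", "L5_pyramidal", "nmda", "proximal", 5e-4, 1.0, 300.0),
    ("L5_pyramidal", "L5_basket", "ampa", "soma", 5e-4, 1.0, 300.0),
    ("L5_basket", "L5_pyramidal", "gabaa", "soma", 5e-2, 1.0, 500.0),
    ("L5_basket", "L5_pyramidal", "gabab", "soma", 5e-3, 1.0, 500.0),
    ("L5_basket", "L5_basket", "gabaa", "soma", 2e-3, 1.0, 500.0),
    # inter-laminar feedforward excitation
    ("L2_pyramidal", "L5_pyramidal", "ampa", "proximal", 2.5e-4, 1.0, 300.0),
    ("L2_pyramidal", "L5_basket", "ampa", "soma", 2.5e-4, 1.0, 300.0),
]


def default_network(grid_shape: Tuple[int, int] = (10, 10),
                    n_basket: int = 35) -> Network:
    """Build the canonical column: per layer, ``grid_shape`` pyramidal
    cells on a 100 µm grid and ``n_basket`` interleaved basket cells,
    with the default connectivity table and no drives.

    The defaults give 100 pyramidal and 35 basket cells in each of
    L2/3 and L5 (270 cells total).
    """
    if grid_shape[0] != grid_shape[1]:
        raise ValueError("grid_shape must be square")
    n_side = grid_shape[0]
    extent = (n_side - 1) * GRID_SPACING
    pops = [
        Population("L2_basket", _basket_grid(n_basket, extent, LAYER_Z["L2"])),
        Population("L2_pyramidal", _pyramidal_grid(n_side, LAYER_Z["L2"])),
        Population("L5_basket", _basket_grid(n_basket, extent, LAYER_Z["L5"])),
        Population("L5_pyramidal", _pyramidal_grid(n_side, LAYER_Z["L5"])),
    ]
    rules = [ConnectionRule(*r[:4], weight=r[4], delay=r[5], space_constant=r[6])
             for r in _DEFAULT_RULES]
    return Network(pops, connectivity=rules)


#: spec-facing alias: the default column is the model the tool ships.
build_default_model = default_network
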