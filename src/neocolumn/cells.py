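"""Reduced multicompartment cell templates.

Four cell classes populate the column model: layer 2/3 and layer 5
pyramidal cells, represented as small compartmental trees with long
apical dendrites aligned to the pial (depth) axis, and one inhibitory
basket-cell class per layer, represented as single-compartment point
neurons.  The apical chain of the pyramidal cells is what carries the
intracellular axial current that sums into the macroscopic current
dipole, so the geometry keeps the L5 apical axis longer than the L2/3
one while everything else stays minimal.

Membrane dynamics are conductance based.  Pyramidal compartments carry
a transient Na current, a delayed-rectifier K current, a slow
muscarinic-type K current (spike-frequency adaptation) and leak; L5
apical compartments additionally carry an L-type Ca current with a
Ca-pool-activated K current.  Basket cells carry Na/K/leak only.  The
leak reversal of every compartment is balanced at build time so that
the stated resting potential is an exact fixed point of the dynamics.

Synapses are bi-exponential conductances (AMPA, NMDA, GABAA, GABAB)
normalised so that a unit event with weight ``w`` peaks at exactly
``w`` microsiemens; NMDA carries the standard sigmoidal magnesium
block.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

CELL_CLASSES: Tuple[str, ...] = (
    "L2_basket",
    "L2_pyramidal",
    "L5_basket",
    "L5_pyramidal",
)
PYRAMIDAL_CLASSES: Tuple[str, ...] = ("L2_pyramidal", "L5_pyramidal")
BASKET_CLASSES: Tuple[str, ...] = ("L2_basket", "L5_basket")
RECEPTORS: Tuple[str, ...] = ("ampa", "nmda", "gabaa", "gabab")
MECHANISM_KINDS: Tuple[str, ...] = (
    "leak",
    "na_transient",
    "k_delayed_rectifier",
    "km_slow",
    "ca_l_type",
    "k_ca",
)

# Reversal potentials (mV) shared by the active mechanisms.
E_NA = 50.0
E_K = -90.0
E_CA = 120.0

# Calcium-pool parameters: a first-order intracellular pool driven by the
# inward L-type current.  Units: concentration in µM, influx factor phi in
# µM cm² / (µA ms), decay time constant in ms.
CA_REST = 0.05
CA_TAU = 50.0
CA_PHI = 0.05
KCA_KD = 1.0  # half-activation of the K(Ca) gate, µM

# NMDA magnesium block constants (Jahr-Stevens form), [Mg] = 1 mM.
MG_SLOPE = 0.062  # 1/mV
MG_SCALE = 3.57  # mM


class UnsupportedCellClassError(ValueError):
    """Raised for a cell class outside the four supported classes."""


class InvalidSynapseSpecError(ValueError):
    """Raised when synapse kinetics violate 0 < tau_rise < tau_decay."""


class TemplateValidationError(ValueError):
    """Raised when a template (or a patch to one) breaks an invariant.

    The message names the offending field.
    """


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompartmentGeometry:
    """A cylindrical compartment in a cell's tree.

    ``z_span`` is the signed projection of the compartment axis on the
    pial (vertical) axis, in µm: positive toward the pia.
    """

    name: str
    length: float  # µm
    diameter: float  # µm
    z_span: float  # signed µm, |z_span| <= length
    parent: Optional[str] = None

    def validate(self) -> None:
        if self.length <= 0:
            raise TemplateValidationError(f"{self.name}.length must be > 0")
        if self.diameter <= 0:
            raise TemplateValidationError(f"{self.name}.diameter must be > 0")
        if abs(self.z_span) > self.length + 1e-12:
            raise TemplateValidationError(
                f"{self.name}.z_span exceeds compartment length"
            )

    @property
    def area_cm2(self) -> float:
        """Lateral (membrane) surface area in cm²."""
        return np.pi * self.diameter * self.length * 1e-8


@dataclass
class MembraneMechanism:
    """A conductance-based membrane mechanism on one compartment."""

    kind: str
    gbar: float  # mS/cm²
    e_rev: float  # mV
    params: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in MECHANISM_KINDS:
            raise TemplateValidationError(f"unknown mechanism kind {self.kind!r}")
        if self.gbar < 0:
            raise TemplateValidationError(f"{self.kind}.gbar must be >= 0")


@dataclass
class SynapseSpec:
    """Bi-exponential synaptic conductance kinetics."""

    receptor: str
    tau_rise: float  # ms
    tau_decay: float  # ms
    e_rev: float  # mV
    mg_block: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise InvalidSynapseSpecError(
                f"{self.receptor}: require 0 < tau_rise ({self.tau_rise}) "
                f"< tau_decay ({self.tau_decay})"
            )

    @property
    def peak_norm(self) -> float:
        """Normalisation so a unit-weight event peaks at exactly 1."""
        tr, td = self.tau_rise, self.tau_decay
        tp = tr * td / (td - tr) * np.log(td / tr)
        return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))


def default_synapses() -> Dict[str, SynapseSpec]:
    return {
        "ampa": SynapseSpec("ampa", 0.5, 5.0, 0.0),
        "nmda": SynapseSpec("nmda", 1.0, 20.0, 0.0, mg_block=True),
        "gabaa": SynapseSpec("gabaa", 0.5, 5.0, -80.0),
        "gabab": SynapseSpec("gabab", 1.0, 20.0, -80.0),
    }


@dataclass
class CellTemplate:
    """Full specification of one cell class.

    Compartments are topologically ordered (parent before child) with the
    soma first; ``synapse_sites`` groups compartments into the proximal /
    distal / somatic targets that drives and connections may address.
    """

    cell_class: str
    compartments: List[CompartmentGeometry]
    mechanisms: Dict[str, List[MembraneMechanism]]
    synapse_sites: Dict[str, List[str]]
    synapses: Dict[str, SynapseSpec] = field(default_factory=default_synapses)
    axial_resistivity: float = 200.0  # Ω·cm
    capacitance: float = 1.0  # µF/cm²
    v_rest: float = -65.0  # mV

    # -- structure helpers ---------------------------------------------------

    @property
    def comp_names(self) -> List[str]:
        return [c.name for c in self.compartments]

    def compartment(self, name: str) -> CompartmentGeometry:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def parent_indices(self) -> np.ndarray:
        """Index of each compartment's parent (-1 for the root)."""
        names = self.comp_names
        idx = []
        for c in self.compartments:
            idx.append(-1 if c.parent is None else names.index(c.parent))
        return np.asarray(idx, dtype=int)

    def apical_chain(self) -> List[str]:
        """Names of compartments with positive z_span, in tree order."""
        return [c.name for c in self.compartments if c.z_span > 0 and c.parent]

    def apical_zextent(self) -> float:
        """Total pial-axis extent of the apical (upward) dendrites, µm."""
        return float(sum(c.z_span for c in self.compartments
                         if c.z_span > 0 and c.parent is not None))

    def z_centers(self) -> np.ndarray:
        """Pial-axis coordinate of each compartment center, soma center at 0."""
        names = self.comp_names
        z_end = {}
        centers = np.zeros(len(names))
        for i, c in enumerate(self.compartments):
            if c.parent is None:
                centers[i] = 0.0
                z_end[c.name] = c.z_span / 2.0
            else:
                base = z_end[c.parent]
                centers[i] = base + c.z_span / 2.0
                z_end[c.name] = base + c.z_span
        return centers

    def axial_conductances(self) -> np.ndarray:
        """Axial conductance (mS) between each non-root compartment and its
        parent, from the two half-cylinder resistances in series."""
        parents = self.parent_indices()
        g = np.zeros(len(self.compartments))
        for i, c in enumerate(self.compartments):
            p = parents[i]
            if p < 0:
                continue
            par = self.compartments[p]
            r = 0.0
            for seg in (c, par):
                length_cm = seg.length * 1e-4 / 2.0
                rad_cm = seg.diameter * 1e-4 / 2.0
                r += self.axial_resistivity * length_cm / (np.pi * rad_cm**2)
            g[i] = 1000.0 / r  # Ω⁻¹ → mS
        return g

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        roots = [c for c in self.compartments if c.parent is None]
        if len(roots) != 1:
            raise TemplateValidationError(
                "compartments: exactly one parentless (soma) compartment required"
            )
        names = self.comp_names
        if len(set(names)) != len(names):
            raise TemplateValidationError("compartments: duplicate names")
        seen = set()
        for c in self.compartments:
            c.validate()
            if c.parent is not None and c.parent not in seen:
                raise TemplateValidationError(
                    f"{c.name}.parent: compartments must be ordered parent-first"
                )
            seen.add(c.name)
        for comp, mechs in self.mechanisms.items():
            if comp not in names:
                raise TemplateValidationError(f"mechanisms.{comp}: unknown compartment")
            for m in mechs:
                m.validate()
        for site, comps in self.synapse_sites.items():
            for comp in comps:
                if comp not in names:
                    raise TemplateValidationError(
                        f"synapse_sites.{site}: unknown compartment {comp!r}"
                    )
        for spec in self.synapses.values():
            if not (0 < spec.tau_rise < spec.tau_decay):
                raise TemplateValidationError(
                    f"synapses.{spec.receptor}.tau_rise: require tau_rise < tau_decay"
                )
        if self.axial_resistivity <= 0:
            raise TemplateValidationError("axial_resistivity must be > 0")
        if self.capacitance <= 0:
            raise TemplateValidationError("capacitance must be > 0")
        if self.cell_class in PYRAMIDAL_CLASSES:
            apical = [c for c in self.compartments if c.z_span > 0 and c.parent]
            if len(apical) < 2:
                raise TemplateValidationError(
                    "compartments: pyramidal template needs an apical chain "
                    "of >= 2 upward compartments"
                )
            if not self.synapse_sites.get("proximal") or not self.synapse_sites.get("distal"):
                raise TemplateValidationError(
                    "synapse_sites: pyramidal templates need non-empty "
                    "proximal and distal groups"
                )
        if self.cell_class in BASKET_CLASSES:
            if len(self.compartments) != 1:
                raise TemplateValidationError(
                    "compartments: basket templates are single-compartment"
                )

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cell_class": self.cell_class,
            "axial_resistivity": self.axial_resistivity,
            "capacitance": self.capacitance,
            "v_rest": self.v_rest,
            "compartments": [
                {
                    "name": c.name,
                    "length": c.length,
                    "diameter": c.diameter,
                    "z_span": c.z_span,
                    "parent": c.parent,
                }
                for c in self.compartments
            ],
            "mechanisms": {
                comp: [
                    {"kind": m.kind, "gbar": m.gbar, "e_rev": m.e_rev,
                     "params": dict(m.params)}
                    for m in mechs
                ]
                for comp, mechs in self.mechanisms.items()
            },
            "synapse_sites": {k: list(v) for k, v in self.synapse_sites.items()},
            "synapses": {
                r: {
                    "receptor": s.receptor,
                    "tau_rise": s.tau_rise,
                    "tau_decay": s.tau_decay,
                    "e_rev": s.e_rev,
                    "mg_block": s.mg_block,
                }
                for r, s in self.synapses.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTemplate":
        tpl = cls(
            cell_class=d["cell_class"],
            compartments=[CompartmentGeometry(**c) for c in d["compartments"]],
            mechanisms={
                comp: [MembraneMechanism(**m) for m in mechs]
                for comp, mechs in d["mechanisms"].items()
            },
            synapse_sites={k: list(v) for k, v in d["synapse_sites"].items()},
            synapses={r: SynapseSpec(**s) for r, s in d["synapses"].items()},
            axial_resistivity=d["axial_resistivity"],
            capacitance=d["capacitance"],
            v_rest=d["v_rest"],
        )
        tpl.validate()
        return tpl

    def copy(self) -> "CellTemplate":
        return copy.deepcopy(self)


@dataclass
class CellState:
    """Instantaneous state of a single cell (per-compartment arrays)."""

    v: np.ndarray  # mV
    gates: Dict[str, np.ndarray]  # gate name -> per-compartment value in [0,1]
    ca: Optional[np.ndarray] = None  # µM per compartment
    syn_conductances: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # (compartment name, receptor) -> µS


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------


def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / k) < 1e-6
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / k))
    return np.where(small, k * (1.0 + x / (2.0 * k)), out)


def na_m_rates(v):
    return 0.32 * _vtrap(v + 54.0, 4.0), 0.28 * _vtrap(-(v + 27.0), 5.0)


def na_h_rates(v):
    v = np.asarray(v, dtype=float)
    return 0.128 * np.exp(-(v + 50.0) / 18.0), 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))


def kdr_n_rates(v):
    v = np.asarray(v, dtype=float)
    return 0.032 * _vtrap(v + 52.0, 5.0), 0.5 * np.exp(-(v + 57.0) / 40.0)


def km_gate(v):
    """(p_inf, tau_p) of the slow muscarinic K gate."""
    v = np.asarray(v, dtype=float)
    p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau = 1000.0 / (3.3 * (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0)))
    return p_inf, tau


def ca_l_gate(v):
    """(q_inf, tau_q) of the L-type Ca activation gate (used squared)."""
    v = np.asarray(v, dtype=float)
    q_inf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 6.0))
    tau = np.full_like(q_inf, 5.0)
    return q_inf, tau


def kca_gate(ca):
    """Instantaneous K(Ca) activation from the Ca pool concentration."""
    ca = np.asarray(ca, dtype=float)
    return ca**2 / (ca**2 + KCA_KD**2)


def mg_block_factor(v):
    """Sigmoidal NMDA magnesium unblock factor in (0, 1)."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-MG_SLOPE * v) / MG_SCALE)


_INF_FUNCS = {
    "na_m": lambda v: na_m_rates(v)[0] / (na_m_rates(v)[0] + na_m_rates(v)[1]),
    "na_h": lambda v: na_h_rates(v)[0] / (na_h_rates(v)[0] + na_h_rates(v)[1]),
    "kdr_n": lambda v: kdr_n_rates(v)[0] / (kdr_n_rates(v)[0] + kdr_n_rates(v)[1]),
    "km_p": lambda v: km_gate(v)[0],
    "ca_q": lambda v: ca_l_gate(v)[0],
}

GATE_NAMES = tuple(_INF_FUNCS)


def steady_state_gates(v) -> Dict[str, np.ndarray]:
    """Voltage-gated steady states at clamped potential ``v``."""
    return {name: np.asarray(fn(v), dtype=float) for name, fn in _INF_FUNCS.items()}


def _mech_gbar(template: CellTemplate, kind: str) -> np.ndarray:
    """Per-compartment gbar (mS/cm²) for one mechanism kind; 0 where absent."""
    g = np.zeros(len(template.compartments))
    for i, c in enumerate(template.compartments):
        for m in template.mechanisms.get(c.name, []):
            if m.kind == kind:
                g[i] += m.gbar
    return g


def _mech_erev(template: CellTemplate, kind: str, default: float) -> np.ndarray:
    e = np.full(len(template.compartments), default)
    for i, c in enumerate(template.compartments):
        for m in template.mechanisms.get(c.name, []):
            if m.kind == kind:
                e[i] = m.e_rev
    return e


def steady_calcium(template: CellTemplate, v: np.ndarray,
                   gates: Mapping[str, np.ndarray]) -> np.ndarray:
    """Fixed point of the Ca pool at clamped voltage ``v`` (µM)."""
    g_ca = _mech_gbar(template, "ca_l_type")
    e_ca = _mech_erev(template, "ca_l_type", E_CA)
    i_ca = g_ca * gates["ca_q"] ** 2 * (np.asarray(v) - e_ca)  # µA/cm²
    return CA_REST - CA_PHI * CA_TAU * i_ca


def resting_state(template: CellTemplate) -> CellState:
    """Cell state at the built-in resting fixed point."""
    n = len(template.compartments)
    v = np.full(n, template.v_rest)
    gates = steady_state_gates(v)
    ca = steady_calcium(template, v, gates)
    return CellState(v=v, gates=gates, ca=ca)


def ionic_current_density(template: CellTemplate, state: CellState) -> np.ndarray:
    """Total ionic membrane current density per compartment, µA/cm².

    Positive = outward.  Excludes synaptic and capacitive terms.
    """
    v = np.asarray(state.v, dtype=float)
    g = state.gates
    i = np.zeros_like(v)
    for kind in MECHANISM_KINDS:
        gbar = _mech_gbar(template, kind)
        if not gbar.any():
            continue
        if kind == "leak":
            e = _mech_erev(template, "leak", template.v_rest)
            i += gbar * (v - e)
        elif kind == "na_transient":
            i += gbar * g["na_m"] ** 3 * g["na_h"] * (v - _mech_erev(template, kind, E_NA))
        elif kind == "k_delayed_rectifier":
            i += gbar * g["kdr_n"] ** 4 * (v - _mech_erev(template, kind, E_K))
        elif kind == "km_slow":
            i += gbar * g["km_p"] * (v - _mech_erev(template, kind, E_K))
        elif kind == "ca_l_type":
            i += gbar * g["ca_q"] ** 2 * (v - _mech_erev(template, kind, E_CA))
        elif kind == "k_ca":
            ca = state.ca if state.ca is not None else np.full_like(v, CA_REST)
            i += gbar * kca_gate(ca) * (v - _mech_erev(template, kind, E_K))
    return i


def balance_leak(template: CellTemplate) -> CellTemplate:
    """Set each compartment's leak reversal so the resting potential is an
    exact fixed point: g_leak (v_rest - e_leak) cancels the summed window
    currents of the other mechanisms at rest.  Mutates and returns."""
    n = len(template.compartments)
    v = np.full(n, template.v_rest)
    gates = steady_state_gates(v)
    ca = steady_calcium(template, v, gates)
    state = CellState(v=v, gates=gates, ca=ca)
    # current with leak e_rev temporarily at v_rest => leak term is 0
    for comp in template.mechanisms.values():
        for m in comp:
            if m.kind == "leak":
                m.e_rev = template.v_rest
    i_other = ionic_current_density(template, state)
    g_leak = _mech_gbar(template, "leak")
    for i, c in enumerate(template.compartments):
        for m in template.mechanisms.get(c.name, []):
            if m.kind == "leak" and g_leak[i] > 0:
                m.e_rev = template.v_rest + i_other[i] / g_leak[i]
    return template


# ---------------------------------------------------------------------------
# template factory
# ---------------------------------------------------------------------------

# (name, parent, length µm, diameter µm, z_span µm)
_GEOMETRY = {
    "L2_pyramidal": [
        ("soma", None, 25.0, 20.0, 25.0),
        ("basal_1", "soma", 100.0, 2.5, -60.0),
        ("basal_2", "soma", 100.0, 2.5, -60.0),
        ("apical_trunk", "soma", 120.0, 3.5, 120.0),
        ("apical_1", "apical_trunk", 150.0, 3.0, 150.0),
        ("apical_tuft", "apical_1", 120.0, 2.5, 120.0),
    ],
    "L5_pyramidal": [
        ("soma", None, 30.0, 25.0, 30.0),
        ("basal_1", "soma", 150.0, 3.0, -80.0),
        ("basal_2", "soma", 150.0, 3.0, -80.0),
        ("apical_trunk", "soma", 200.0, 4.0, 200.0),
        ("apical_1", "apical_trunk", 250.0, 3.5, 250.0),
        ("apical_2", "apical_1", 250.0, 3.0, 250.0),
        ("apical_tuft", "apical_2", 150.0, 2.5, 150.0),
    ],
    "L2_basket": [("soma", None, 25.0, 20.0, 25.0)],
    "L5_basket": [("soma", None, 25.0, 20.0, 25.0)],
}

_SITES = {
    "L2_pyramidal": {
        "proximal": ["basal_1", "basal_2", "apical_trunk"],
        "distal": ["apical_tuft"],
        "soma": ["soma"],
    },
    "L5_pyramidal": {
        "proximal": ["basal_1", "basal_2", "apical_trunk"],
        "distal": ["apical_tuft"],
        "soma": ["soma"],
    },
    "L2_basket": {"soma": ["soma"]},
    "L5_basket": {"soma": ["soma"]},
}

# gbar in mS/cm²
_PYR_SOMA = [("leak", 0.05), ("na_transient", 150.0),
             ("k_delayed_rectifier", 100.0), ("km_slow", 1.0)]
_PYR_DEND = [("leak", 0.05), ("na_transient", 15.0),
             ("k_delayed_rectifier", 10.0), ("km_slow", 0.5)]
_L5_APIC_EXTRA = [("ca_l_type", 0.5), ("k_ca", 2.0)]
_BASKET_SOMA = [("leak", 0.1), ("na_transient", 150.0),
                ("k_delayed_rectifier", 100.0)]

_DEFAULT_EREV = {
    "leak": -65.0,
    "na_transient": E_NA,
    "k_delayed_rectifier": E_K,
    "km_slow": E_K,
    "ca_l_type": E_CA,
    "k_ca": E_K,
}


def _mechs(pairs) -> List[MembraneMechanism]:
    return [MembraneMechanism(kind, gbar, _DEFAULT_EREV[kind]) for kind, gbar in pairs]


def build_template(cell_class: str) -> CellTemplate:
    """Build the default template for one of the four supported classes.

    Deterministic: repeated calls return identical templates.
    """
    if cell_class not in CELL_CLASSES:
        raise UnsupportedCellClassError(
            f"unsupported cell class {cell_class!r}; expected one of {CELL_CLASSES}"
        )
    comps = [CompartmentGeometry(name, length=length, diameter=diam, z_span=z,
                                 parent=parent)
             for name, parent, length, diam, z in _GEOMETRY[cell_class]]
    mechanisms: Dict[str, List[MembraneMechanism]] = {}
    for c in comps:
        if cell_class in BASKET_CLASSES:
            mechanisms[c.name] = _mechs(_BASKET_SOMA)
        elif c.name == "soma":
            mechanisms[c.name] = _mechs(_PYR_SOMA)
        else:
            pairs = list(_PYR_DEND)
            if cell_class == "L5_pyramidal" and c.name.startswith("apical"):
                pairs += _L5_APIC_EXTRA
            mechanisms[c.name] = _mechs(pairs)
    tpl = CellTemplate(
        cell_class=cell_class,
        compartments=comps,
        mechanisms=mechanisms,
        synapse_sites={k: list(v) for k, v in _SITES[cell_class].items()},
    )
    balance_leak(tpl)
    tpl.validate()
    return tpl


# ---------------------------------------------------------------------------
# synaptic conductance (analytic superposition)
# ---------------------------------------------------------------------------


def synaptic_conductance(spec: SynapseSpec, event_times: Sequence[float],
                         weight: float, t, v: Optional[float] = None):
    """Conductance (µS) at time(s) ``t`` from bi-exponential superposition.

    Each event contributes ``weight`` at its peak; contributions add
    linearly.  For an NMDA spec with ``mg_block`` and a supplied membrane
    potential ``v`` the result is scaled by the magnesium unblock factor.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    norm = spec.peak_norm
    for t_ev in event_times:
        dt = t - t_ev
        active = dt >= 0
        g = g + np.where(
            active,
            weight * norm * (np.exp(-np.clip(dt, 0, None) / spec.tau_decay)
                             - np.exp(-np.clip(dt, 0, None) / spec.tau_rise)),
            0.0,
        )
    if spec.mg_block and v is not None:
        g = g * mg_block_factor(v)
    return g if g.shape else float(g)


def transmembrane_currents(template: CellTemplate, state: CellState) -> np.ndarray:
    """Ionic + synaptic membrane current density per compartment, µA/cm².

    Positive = outward.  The capacitive term is excluded ("capacitive-free"):
    this is the current that the membrane conductances pass at the given
    state, the quantity entering the dipole/LFP bookkeeping.
    """
    n = len(template.compartments)
    if np.asarray(state.v).shape != (n,):
        raise ValueError(
            f"state has {np.asarray(state.v).shape} voltages for "
            f"{n} compartments"
        )
    i = ionic_current_density(template, state)
    names = template.comp_names
    for (comp, receptor), g_us in state.syn_conductances.items():
        spec = template.synapses[receptor]
        idx = names.index(comp)
        g_ms = g_us * 1e-3
        if spec.mg_block:
            g_ms *= mg_block_factor(state.v[idx])
        # absolute µA -> density via the compartment area
        i[idx] += g_ms * (state.v[idx] - spec.e_rev) / template.compartments[idx].area_cm2
    return i
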