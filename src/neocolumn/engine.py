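"""Numerical integration of the column model.

Voltages advance by an implicit (backward-Euler) update of the cable
equation on each cell's compartmental tree — membrane and synaptic
conductances are frozen over the step, making the update a small linear
solve per cell, unconditionally stable on trees.  Gating variables
advance by exponential Euler using the voltage at step start.  Synaptic
conductances are carried as pairs of exponentially decaying states (the
closed-form of the bi-exponential kernel), so event delivery is an
instantaneous state increment and superposition is exact.

Spikes are detected on the upward 0 mV crossing of the soma voltage
(3 ms refractory, detection only — the dynamics stay continuous) and
propagate through the connectivity table as delayed conductance events.

Each trial is deterministic given (network, settings); trials differ
only in their drive seeds and share no mutable state, so they can be
mapped over any executor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import cells as _c
from .cells import CellTemplate, PYRAMIDAL_CLASSES, RECEPTORS
from .drives import drive_seed
from .network import Network
from .recordings import point_source_transfer

REFRACTORY_MS = 3.0
SPIKE_THRESHOLD_MV = 0.0


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class SimulationSettings:
    """Integration and trial settings."""

    tstop: float  # ms
    dt: float = 0.025  # ms
    n_trials: int = 1
    master_seed: int = 0
    record_voltages: bool = False

    def __post_init__(self) -> None:
        if self.tstop <= 0:
            raise ValueError("tstop must be > 0")
        if not (0 < self.dt <= 0.1):
            raise ValueError("dt must satisfy 0 < dt <= 0.1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class RawTrialResult:
    """Raw per-trial output handed to the recordings layer."""

    trial: int
    dt: float
    times: np.ndarray  # ms, n_steps + 1 samples
    spike_times: np.ndarray  # ms
    spike_gids: np.ndarray
    gid_to_class: Dict[int, str]
    dipole_layers: Dict[str, np.ndarray]  # layer -> nAm per sample
    templates: Dict[str, CellTemplate]
    voltages: Optional[Dict[str, np.ndarray]] = None  # class -> (n_t, n_cells, n_comp)
    axial_currents: Optional[Dict[str, np.ndarray]] = None  # nA, child-indexed
    tm_currents: Optional[Dict[str, np.ndarray]] = None  # nA per compartment
    comp_centers: Optional[Dict[str, np.ndarray]] = None  # µm (n_cells, n_comp, 3)
    lfp: Optional[List[np.ndarray]] = None  # per array: (n_elec, n_t) µV
    drive_events: Dict[str, List[np.ndarray]] = field(default_factory=dict)


class _Group:
    """State arrays for all cells of one class (vectorised over cells)."""

    def __init__(self, cell_class: str, template: CellTemplate,
                 positions: np.ndarray, dt: float):
        self.cell_class = cell_class
        self.template = template
        self.positions = np.asarray(positions, dtype=float)
        self.n_cells = len(positions)
        self.n_comp = len(template.compartments)
        self.dt = dt

        parents = template.parent_indices()
        self.parents = parents
        areas = np.array([c.area_cm2 for c in template.compartments])
        self.areas = areas
        self.c_abs = template.capacitance * areas  # µF
        g_pair = template.axial_conductances()  # mS, child-indexed
        self.g_pair = g_pair
        lap = np.zeros((self.n_comp, self.n_comp))
        for child, p in enumerate(parents):
            if p < 0:
                continue
            g = g_pair[child]
            lap[child, child] += g
            lap[p, p] += g
            lap[child, p] -= g
            lap[p, child] -= g
        self.g_lap = lap

        z_rel = template.z_centers()
        self.z_rel = z_rel
        # dipole moment per mV of parent-child voltage difference, nAm:
        # i_nA = 1e3 * g_pair * (v_p - v_c);  p = i_nA * dz_µm * 1e-6
        dz = np.zeros(self.n_comp)
        for child, p in enumerate(parents):
            if p >= 0:
                dz[child] = z_rel[child] - z_rel[p]
        self.dz_pair = dz
        self.w_pair = g_pair * dz * 1e-3

        # mechanism conductances, absolute mS per compartment
        self.g_leak = _c._mech_gbar(template, "leak") * areas
        self.e_leak = _c._mech_erev(template, "leak", template.v_rest)
        self.g_na = _c._mech_gbar(template, "na_transient") * areas
        self.e_na = _c._mech_erev(template, "na_transient", _c.E_NA)
        self.g_kdr = _c._mech_gbar(template, "k_delayed_rectifier") * areas
        self.e_k = _c._mech_erev(template, "k_delayed_rectifier", _c.E_K)
        self.g_km = _c._mech_gbar(template, "km_slow") * areas
        self.e_km = _c._mech_erev(template, "km_slow", _c.E_K)
        self.g_ca = _c._mech_gbar(template, "ca_l_type") * areas
        self.e_ca = _c._mech_erev(template, "ca_l_type", _c.E_CA)
        self.g_kca = _c._mech_gbar(template, "k_ca") * areas
        self.e_kca = _c._mech_erev(template, "k_ca", _c.E_K)
        self.g_ca_dens = _c._mech_gbar(template, "ca_l_type")  # density for pool
        self.has_ca = bool(self.g_ca.any())
        self.has_km = bool(self.g_km.any())

        # synapse bookkeeping: receptor-indexed decaying state pairs (mS)
        self.receptors = list(RECEPTORS)
        self.syn_specs = [template.synapses[r] for r in self.receptors]
        self.syn_e = np.array([s.e_rev for s in self.syn_specs])
        self.syn_norm = np.array([s.peak_norm for s in self.syn_specs])
        self.syn_mg = np.array([s.mg_block for s in self.syn_specs])
        self.dec_rise = np.array(
            [np.exp(-dt / s.tau_rise) for s in self.syn_specs])[:, None, None]
        self.dec_decay = np.array(
            [np.exp(-dt / s.tau_decay) for s in self.syn_specs])[:, None, None]
        self.syn_a = np.zeros((len(self.receptors), self.n_cells, self.n_comp))
        self.syn_b = np.zeros_like(self.syn_a)

        self.site_comps = {
            site: np.array([template.comp_names.index(n) for n in comps], dtype=int)
            for site, comps in template.synapse_sites.items()
        }

        # initial state: the built-in resting fixed point
        self.v = np.full((self.n_cells, self.n_comp), template.v_rest)
        gates0 = _c.steady_state_gates(np.full(self.n_comp, template.v_rest))
        self.gates = {k: np.tile(g, (self.n_cells, 1)) for k, g in gates0.items()}
        ca0 = _c.steady_calcium(template, np.full(self.n_comp, template.v_rest), gates0)
        self.ca = np.tile(ca0, (self.n_cells, 1))
        self.last_spike = np.full(self.n_cells, -np.inf)
        self.i_inj = np.zeros((self.n_cells, self.n_comp))  # µA
        self.tonic: List[Tuple[float, float, float]] = []  # (amp µA, t_start, t_stop)

        # membrane-current-per-compartment work (for LFP): I_tm = -G v + I_inj
        self._eye_scaled = None

    def comp_centers(self) -> np.ndarray:
        """(n_cells, n_comp, 3) compartment centers, µm."""
        out = np.empty((self.n_cells, self.n_comp, 3))
        out[:, :, 0] = self.positions[:, 0:1]
        out[:, :, 1] = self.positions[:, 1:2]
        out[:, :, 2] = self.positions[:, 2:3] + self.z_rel[None, :]
        return out

    # -- per-step pieces -----------------------------------------------------

    def update_gates(self) -> None:
        v = self.v
        dt = self.dt
        for name, rates in (("na_m", _c.na_m_rates), ("na_h", _c.na_h_rates),
                            ("kdr_n", _c.kdr_n_rates)):
            a, b = rates(v)
            tot = a + b
            inf = a / tot
            x = self.gates[name]
            self.gates[name] = inf + (x - inf) * np.exp(-dt * tot)
        gate_funcs = []
        if self.has_km:
            gate_funcs.append(("km_p", _c.km_gate))
        if self.has_ca:
            gate_funcs.append(("ca_q", _c.ca_l_gate))
        for name, gate in gate_funcs:
            inf, tau = gate(v)
            x = self.gates[name]
            self.gates[name] = inf + (x - inf) * np.exp(-dt / tau)
        if self.has_ca:
            i_ca = self.g_ca_dens[None, :] * self.gates["ca_q"] ** 2 \
                * (v - self.e_ca[None, :])  # µA/cm²
            ca_inf = _c.CA_REST - _c.CA_PHI * _c.CA_TAU * i_ca
            self.ca = ca_inf + (self.ca - ca_inf) * np.exp(-dt / _c.CA_TAU)
            np.clip(self.ca, 0.0, None, out=self.ca)

    def decay_synapses(self) -> None:
        self.syn_a *= self.dec_rise
        self.syn_b *= self.dec_decay

    def apply_increments(self, rec_idx: int, cells: np.ndarray,
                         comps: np.ndarray, w_ms: np.ndarray) -> None:
        inc = w_ms * self.syn_norm[rec_idx]
        np.add.at(self.syn_a[rec_idx], (cells, comps), inc)
        np.add.at(self.syn_b[rec_idx], (cells, comps), inc)

    def conductance_terms(self) -> Tuple[np.ndarray, np.ndarray]:
        """(g_total, g_times_e) per cell/compartment, mS and mS·mV."""
        g = self.gates
        v = self.v
        g_na = self.g_na[None, :] * g["na_m"] ** 3 * g["na_h"]
        g_kdr = self.g_kdr[None, :] * g["kdr_n"] ** 4
        g_tot = self.g_leak[None, :] + g_na + g_kdr
        ge = (self.g_leak * self.e_leak)[None, :] + g_na * self.e_na[None, :] \
            + g_kdr * self.e_k[None, :]
        if self.has_km:
            g_km = self.g_km[None, :] * g["km_p"]
            g_tot = g_tot + g_km
            ge = ge + g_km * self.e_km[None, :]
        if self.has_ca:
            g_cal = self.g_ca[None, :] * g["ca_q"] ** 2
            g_kca = self.g_kca[None, :] * _c.kca_gate(self.ca)
            g_tot = g_tot + g_cal + g_kca
            ge = ge + g_cal * self.e_ca[None, :] + g_kca * self.e_kca[None, :]
        # synapses
        g_syn = self.syn_b - self.syn_a  # (n_rec, n_cells, n_comp), mS
        for k, spec in enumerate(self.syn_specs):
            gk = g_syn[k]
            if not gk.any():
                continue
            if self.syn_mg[k]:
                gk = gk * _c.mg_block_factor(v)
            g_tot = g_tot + gk
            ge = ge + gk * self.syn_e[k]
        return g_tot, ge

    def injected(self, t: float) -> np.ndarray:
        if not self.tonic:
            return self.i_inj
        out = self.i_inj.copy()
        for amp, t0, t1 in self.tonic:
            if t0 <= t and (t1 is None or t <= t1):
                out[:, 0] += amp
        return out

    def advance_voltage(self, t_new: float) -> np.ndarray:
        """Backward-Euler solve; returns previous voltage."""
        g_tot, ge = self.conductance_terms()
        cdt = self.c_abs / self.dt  # mS-equivalent (µF/ms)
        rhs = cdt[None, :] * self.v + ge + self.injected(t_new)
        v_old = self.v
        if self.n_comp == 1:
            diag = cdt[None, :] + g_tot
            self.v = rhs / diag
        else:
            a_mat = np.broadcast_to(
                self.g_lap, (self.n_cells, self.n_comp, self.n_comp)).copy()
            idx = np.arange(self.n_comp)
            a_mat[:, idx, idx] += cdt[None, :] + g_tot
            self.v = np.linalg.solve(a_mat, rhs[:, :, None])[:, :, 0]
        return v_old

    def detect_spikes(self, v_old: np.ndarray, t_new: float) -> np.ndarray:
        crossing = (self.v[:, 0] >= SPIKE_THRESHOLD_MV) \
            & (v_old[:, 0] < SPIKE_THRESHOLD_MV) \
            & (t_new - self.last_spike >= REFRACTORY_MS)
        spikers = np.nonzero(crossing)[0]
        if spikers.size:
            self.last_spike[spikers] = t_new
        return spikers

    def dipole_moment(self) -> float:
        """Net pial-axis dipole moment of this group's cells, nAm.

        Current flowing from deep to superficial (toward the pia) counts
        positive.
        """
        v_p = self.v[:, np.maximum(self.parents, 0)]
        return float(np.sum(self.w_pair[None, :] * (v_p - self.v)))

    def axial_pair_currents(self) -> np.ndarray:
        """(n_cells, n_comp) parent->child axial currents, nA (0 for root)."""
        v_p = self.v[:, np.maximum(self.parents, 0)]
        i = 1e3 * self.g_pair[None, :] * (v_p - self.v)
        i[:, self.parents < 0] = 0.0
        return i

    def membrane_currents(self, t: float) -> np.ndarray:
        """(n_cells, n_comp) net outward membrane current, nA.

        By current conservation this equals axial inflow plus injection,
        so it sums (per isolated cell) to the injected current.
        """
        ax_in = -np.einsum("jk,ck->cj", self.g_lap, self.v)
        return 1e3 * (ax_in + self.injected(t))


@dataclass
class _Bucket:
    """Pending conductance increments for one future step."""

    items: Dict[Tuple[int, int], List[Tuple[np.ndarray, np.ndarray, np.ndarray]]] \
        = field(default_factory=dict)

    def add(self, group: int, rec: int, cells, comps, w_ms) -> None:
        self.items.setdefault((group, rec), []).append(
            (np.atleast_1d(cells), np.atleast_1d(comps), np.atleast_1d(w_ms)))


class SimulationState:
    """Full integrator state for one trial; ``step()`` advances by dt."""

    def __init__(self, net: Network, settings: SimulationSettings, trial: int = 0,
                 extracellular: Optional[Sequence] = None):
        self.net = net
        self.settings = settings
        self.trial = trial
        self.dt = settings.dt
        self.n_steps = int(round(settings.tstop / settings.dt))
        self.step_index = 0
        self.t = 0.0

        self.groups: List[_Group] = []
        self.group_index: Dict[str, int] = {}
        for pop in net.populations:
            g = _Group(pop.cell_class, net.templates[pop.cell_class],
                       np.asarray(pop.positions), settings.dt)
            self.group_index[pop.cell_class] = len(self.groups)
            self.groups.append(g)
        self.gid_ranges = net.gid_ranges()

        self.buckets: Dict[int, _Bucket] = {}
        self.spike_times: List[float] = []
        self.spike_gids: List[int] = []
        self.drive_events: Dict[str, List[np.ndarray]] = {}
        self._rules = [(r, net.pair_weights(r)) for r in net.connectivity]
        self._rules_by_src: Dict[int, List[int]] = {}
        for i, (r, _) in enumerate(self._rules):
            self._rules_by_src.setdefault(self.group_index[r.src_class], []).append(i)

        self._schedule_drives()

        # extracellular recording
        self.arrays = list(extracellular or [])
        self._transfer: List[List[np.ndarray]] = []
        for arr in self.arrays:
            mats = []
            for g in self.groups:
                centers = g.comp_centers().reshape(-1, 3)
                radii = np.tile(
                    [c.diameter / 2.0 for c in g.template.compartments],
                    g.n_cells)
                mats.append(point_source_transfer(
                    np.asarray(arr.positions, dtype=float), centers,
                    arr.sigma, radii))
            self._transfer.append(mats)

    # -- drive scheduling ----------------------------------------------------

    def _bucket_for_time(self, t: float) -> _Bucket:
        idx = int(np.ceil(t / self.dt - 1e-9))
        idx = max(idx, self.step_index + 1)
        return self.buckets.setdefault(idx, _Bucket())

    def _schedule_drives(self) -> None:
        for k, drive in enumerate(self.net.drives):
            if drive.kind == "tonic":
                for cls, amp in drive.amplitudes.items():
                    g = self.groups[self.group_index[cls]]
                    g.tonic.append((amp * 1e-3, drive.t_start, drive.t_stop))
                continue
            rng = np.random.default_rng(
                drive_seed(self.settings.master_seed, self.trial, k, drive.seed))
            all_events = []
            for cls, site in self.net.drive_targets(drive):
                gi = self.group_index[cls]
                group = self.groups[gi]
                comps = group.site_comps[site]
                delay = drive.synaptic_delays[cls]
                weights = {rec: per_cls[cls]
                           for rec, per_cls in drive.weights.items()
                           if cls in per_cls}
                for cell in range(group.n_cells):
                    events = drive.unit_events(rng)
                    all_events.append(events)
                    for t_ev in events:
                        bucket = self._bucket_for_time(t_ev + delay)
                        for rec, w in weights.items():
                            rec_idx = RECEPTORS.index(rec)
                            w_ms = np.full(len(comps),
                                           w * 1e-3 / len(comps))
                            bucket.add(gi, rec_idx,
                                       np.full(len(comps), cell), comps, w_ms)
            self.drive_events[drive.name] = all_events

    # -- stepping ------------------------------------------------------------

    def step(self) -> None:
        """Advance every cell by one dt."""
        self.step_index += 1
        t_new = self.step_index * self.dt  # same grid as the recorded times
        for g in self.groups:
            g.update_gates()
            g.decay_synapses()
        bucket = self.buckets.pop(self.step_index, None)
        if bucket is not None:
            for (gi, rec), chunks in bucket.items.items():
                cells = np.concatenate([c[0] for c in chunks])
                comps = np.concatenate([c[1] for c in chunks])
                w = np.concatenate([c[2] for c in chunks])
                self.groups[gi].apply_increments(rec, cells, comps, w)
        for gi, g in enumerate(self.groups):
            v_old = g.advance_voltage(t_new)
            if not np.isfinite(g.v).all():
                bad = np.argwhere(~np.isfinite(g.v))[0]
                raise IntegrationError(
                    f"non-finite voltage in {g.cell_class} cell {bad[0]} "
                    f"at t = {t_new:.3f} ms")
            spikers = g.detect_spikes(v_old, t_new)
            for cell in spikers:
                self._emit_spike(gi, int(cell), t_new)
        self.t = t_new

    def _emit_spike(self, gi: int, cell: int, t: float) -> None:
        cls = self.groups[gi].cell_class
        self.spike_times.append(t)
        self.spike_gids.append(self.gid_ranges[cls][cell])
        for ridx in self._rules_by_src.get(gi, []):
            rule, w_mat = self._rules[ridx]
            w_row = w_mat[cell]
            dst = np.nonzero(w_row)[0]
            if not dst.size:
                continue
            dst_gi = self.group_index[rule.dst_class]
            comps = self.groups[dst_gi].site_comps[rule.target_site]
            n_site = len(comps)
            cells = np.repeat(dst, n_site)
            comp_arr = np.tile(comps, dst.size)
            w_ms = np.repeat(w_row[dst] * 1e-3 / n_site, n_site)
            bucket = self._bucket_for_time(t + rule.delay)
            bucket.add(dst_gi, RECEPTORS.index(rule.receptor),
                       cells, comp_arr, w_ms)

    def dipole_layers(self) -> Dict[str, float]:
        out = {"L2": 0.0, "L5": 0.0}
        for g in self.groups:
            if g.cell_class in PYRAMIDAL_CLASSES:
                out[g.cell_class.split("_")[0]] += g.dipole_moment()
        return out


def step(state: SimulationState) -> SimulationState:
    """Advance a simulation state by one integration step (in place)."""
    state.step()
    return state


def _run_trial(net: Network, settings: SimulationSettings, trial: int,
               extracellular: Optional[Sequence], record_currents: bool
               ) -> RawTrialResult:
    state = SimulationState(net, settings, trial, extracellular)
    n_t = state.n_steps + 1
    times = np.arange(n_t) * settings.dt
    dip = {"L2": np.zeros(n_t), "L5": np.zeros(n_t)}
    voltages = ({g.cell_class: np.zeros((n_t, g.n_cells, g.n_comp))
                 for g in state.groups} if settings.record_voltages else None)
    axial = ({g.cell_class: np.zeros((n_t, g.n_cells, g.n_comp))
              for g in state.groups} if record_currents else None)
    tm = ({g.cell_class: np.zeros((n_t, g.n_cells, g.n_comp))
           for g in state.groups} if record_currents else None)
    lfp = ([np.zeros((len(arr.positions), n_t)) for arr in state.arrays]
           if state.arrays else None)

    def record(i: int) -> None:
        d = state.dipole_layers()
        dip["L2"][i] = d["L2"]
        dip["L5"][i] = d["L5"]
        for gi, g in enumerate(state.groups):
            if voltages is not None:
                voltages[g.cell_class][i] = g.v
            if axial is not None:
                axial[g.cell_class][i] = g.axial_pair_currents()
            if tm is not None:
                tm[g.cell_class][i] = g.membrane_currents(state.t)
        if lfp is not None:
            for ai in range(len(state.arrays)):
                phi = np.zeros(lfp[ai].shape[0])
                for gi, g in enumerate(state.groups):
                    i_tm = g.membrane_currents(state.t).ravel()
                    phi += state._transfer[ai][gi] @ i_tm
                lfp[ai][:, i] = phi

    record(0)
    for i in range(1, n_t):
        state.step()
        record(i)

    order = np.argsort(state.spike_times, kind="stable")
    return RawTrialResult(
        trial=trial,
        dt=settings.dt,
        times=times,
        spike_times=np.asarray(state.spike_times)[order],
        spike_gids=np.asarray(state.spike_gids, dtype=int)[order],
        gid_to_class=net.gid_to_class(),
        dipole_layers=dip,
        templates=net.templates,
        voltages=voltages,
        axial_currents=axial,
        tm_currents=tm,
        comp_centers={g.cell_class: g.comp_centers() for g in state.groups},
        lfp=lfp,
        drive_events=state.drive_events,
    )


def simulate(net: Network, settings: SimulationSettings,
             extracellular: Optional[Sequence] = None,
             record_currents: bool = False,
             trial_map: Optional[Callable] = None) -> List[RawTrialResult]:
    """Run ``settings.n_trials`` independent trials.

    Trials differ only in drive seeds (master_seed + 1000·trial + drive
    index) and are keyed by trial index, so results are independent of
    execution order.  ``trial_map`` is an optional parallel map hook with
    the signature of :func:`map`; the default runs trials serially.
    """
    runner = trial_map if trial_map is not None else map
    return list(runner(
        lambda trial: _run_trial(net, settings, trial, extracellular,
                                 record_currents),
        range(settings.n_trials)))


def simulate_dipole(net: Network, tstop: float, dt: float = 0.025,
                    n_trials: int = 1, master_seed: int = 0,
                    record_voltages: bool = False):
    """Convenience wrapper: simulate and return one DipoleRecord per trial."""
    from .recordings import compute_dipole

    settings = SimulationSettings(tstop=tstop, dt=dt, n_trials=n_trials,
                                  master_seed=master_seed,
                                  record_voltages=record_voltages)
    return [compute_dipole(raw) for raw in simulate(net, settings)]
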