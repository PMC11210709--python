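"""Observables derived from raw simulation trajectories.

The net primary current dipole is the axial intracellular current in
the pyramidal dendrites weighted by the pial-axis separation it flows
across, summed per layer — the quantity MEG/EEG source estimates report
(nAm).  Extracellular potentials use the point-source approximation in
an infinite homogeneous medium, and the laminar current-source density
is the standard second spatial difference of the depth profile.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import convolve

DEFAULT_SIGMA_S_PER_M = 0.3  # extracellular conductivity
DEFAULT_SMOOTH_SAMPLES = 30


@dataclass
class DipoleRecord:
    """Net primary current dipole time series, decomposed by layer.

    ``aggregate = layers['L2'] + layers['L5']`` holds exactly on the raw
    record; smoothing and scaling return modified copies that keep a
    reference to the unprocessed record in ``raw``.
    """

    times: np.ndarray  # ms
    layers: Dict[str, np.ndarray]  # nAm per layer
    aggregate: np.ndarray  # nAm
    scaling: float = 1.0
    smoothing_window_ms: float = 0.0
    raw: Optional["DipoleRecord"] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.aggregate):
            raise ValueError("times and aggregate must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def _base(self) -> "DipoleRecord":
        return self.raw if self.raw is not None else self

    def smooth(self, window_ms: Optional[float] = None) -> "DipoleRecord":
        """Hamming-window smoothing; default window is 30 samples."""
        if window_ms is None:
            n_win = DEFAULT_SMOOTH_SAMPLES
            window_ms = n_win * self.dt
        else:
            n_win = max(int(round(window_ms / self.dt)), 1)
        win = np.hamming(n_win)
        win /= win.sum()

        def _smooth(x):
            pad = n_win // 2
            xp = np.pad(x, pad, mode="edge")
            return convolve(xp, win, mode="same")[pad:pad + len(x)]

        layers = {k: _smooth(v) for k, v in self.layers.items()}
        return DipoleRecord(
            times=self.times.copy(),
            layers=layers,
            aggregate=_smooth(self.aggregate),
            scaling=self.scaling,
            smoothing_window_ms=window_ms,
            raw=self._base(),
        )

    def scale(self, factor: float) -> "DipoleRecord":
        """Multiply the dipole by a user scaling factor (copy)."""
        return DipoleRecord(
            times=self.times.copy(),
            layers={k: v * factor for k, v in self.layers.items()},
            aggregate=self.aggregate * factor,
            scaling=self.scaling * factor,
            smoothing_window_ms=self.smoothing_window_ms,
            raw=self._base(),
        )

    def copy(self) -> "DipoleRecord":
        return _copy.deepcopy(self)

    def plot(self, ax=None, show_layers: bool = True):
        """Plot the dipole waveform (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.aggregate, "k", label="aggregate")
        if show_layers:
            for name, trace in self.layers.items():
                ax.plot(self.times, trace, alpha=0.6, label=name)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("dipole (nAm)")
        ax.legend()
        return ax


@dataclass
class CellResponse:
    """Spiking output of one trial."""

    spike_times: np.ndarray  # ms, sorted
    spike_gids: np.ndarray
    gid_to_class: Dict[int, str]

    def __post_init__(self) -> None:
        for gid in np.unique(self.spike_gids):
            if int(gid) not in self.gid_to_class:
                raise ValueError(f"spike gid {gid} has no cell class")

    def times_for_class(self, cell_class: str) -> np.ndarray:
        mask = np.array([self.gid_to_class[int(g)] == cell_class
                         for g in self.spike_gids], dtype=bool)
        if not len(self.spike_times):
            return np.empty(0)
        return self.spike_times[mask]

    def plot_raster(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.spike_times, self.spike_gids, "|", markersize=3)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("cell gid")
        return ax


@dataclass
class ExtracellularArray:
    """Electrode positions plus recorded potentials.

    Point-source forward model: φ(e, t) = Σ_c I_tm(c, t) / (4πσ r(e, c)).
    """

    positions: List[Tuple[float, float, float]]  # µm
    sigma: float = DEFAULT_SIGMA_S_PER_M  # S/m
    method: str = "point_source"
    voltages: Optional[np.ndarray] = None  # (n_elec, n_t) µV
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.method != "point_source":
            raise ValueError(f"unknown LFP method {self.method!r}")
        if self.voltages is not None and self.times is not None:
            if self.voltages.shape[1] != len(self.times):
                raise ValueError("voltages second axis must match times")


def point_source_transfer(elec_pos: np.ndarray, src_pos: np.ndarray,
                          sigma: float,
                          min_distance: Optional[np.ndarray] = None
                          ) -> np.ndarray:
    """(n_elec, n_src) map from nA point-source currents to µV potentials.

    ``min_distance`` (µm per source, e.g. compartment radius) makes an
    electrode inside a source an error.
    """
    elec_pos = np.asarray(elec_pos, dtype=float)
    src_pos = np.asarray(src_pos, dtype=float)
    d = np.linalg.norm(elec_pos[:, None, :] - src_pos[None, :, :], axis=2)
    if min_distance is not None:
        too_close = d < np.asarray(min_distance)[None, :]
        if too_close.any():
            e, c = np.argwhere(too_close)[0]
            raise ValueError(
                f"electrode {e} lies inside source {c} (r = {d[e, c]:.2f} µm)")
    elif (d == 0).any():
        raise ValueError("electrode coincides with a source")
    r_m = d * 1e-6
    # φ[µV] = 1e6 · (I[nA]·1e-9) / (4πσ r) = 1e-3 · I[nA] / (4πσ r[m])
    return 1e-3 / (4.0 * np.pi * sigma * r_m)


def dipole_from_axial(i_axial_nA: np.ndarray, dz_um: np.ndarray) -> np.ndarray:
    """Dipole moment (nAm) from axial currents (nA) across pial-axis
    center separations (µm): p(t) = Σ_pairs i(t) · Δz · 1e-6.

    ``i_axial_nA`` has shape (..., n_pairs) or (n_t, n_pairs); the pair
    axis is summed.  Linear in the currents by construction.
    """
    i_axial_nA = np.asarray(i_axial_nA, dtype=float)
    dz_um = np.asarray(dz_um, dtype=float)
    return (i_axial_nA * dz_um).sum(axis=-1) * 1e-6


def compute_dipole(raw) -> DipoleRecord:
    """Package the per-layer dipole of one raw trial as a DipoleRecord."""
    layers = {k: np.asarray(v, dtype=float).copy()
              for k, v in raw.dipole_layers.items()}
    aggregate = sum(layers.values())
    return DipoleRecord(times=np.asarray(raw.times, dtype=float).copy(),
                        layers=layers, aggregate=np.asarray(aggregate))


def cell_response(raw) -> CellResponse:
    return CellResponse(spike_times=raw.spike_times, spike_gids=raw.spike_gids,
                        gid_to_class=raw.gid_to_class)


def compute_lfp(raw, array: ExtracellularArray) -> ExtracellularArray:
    """Fill an electrode array with potentials from a trial's membrane
    currents (requires the trial to have been run with current recording).
    """
    if raw.tm_currents is None or raw.comp_centers is None:
        raise ValueError("trial was run without membrane-current recording")
    elec = np.asarray(array.positions, dtype=float)
    n_t = len(raw.times)
    phi = np.zeros((len(elec), n_t))
    for cls, currents in raw.tm_currents.items():
        centers = raw.comp_centers[cls].reshape(-1, 3)
        diam = np.tile([c.diameter for c in raw.templates[cls].compartments],
                       raw.comp_centers[cls].shape[0])
        m = point_source_transfer(elec, centers, array.sigma, diam / 2.0)
        flat = currents.reshape(n_t, -1)  # (n_t, n_src) nA
        phi += m @ flat.T
    return ExtracellularArray(positions=list(array.positions), sigma=array.sigma,
                              method=array.method, voltages=phi,
                              times=np.asarray(raw.times).copy())


def compute_csd(array: ExtracellularArray,
                rtol: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    """Laminar current-source density from an equally spaced depth profile.

    CSD(z, t) = -σ · (φ(z+h) - 2φ(z) + φ(z-h)) / h² at the interior
    electrodes, with h the electrode spacing in µm.  Returns
    (interior depths µm, CSD array of shape (n_interior, n_t)).
    Sinks (inward membrane current) appear negative.
    """
    if array.voltages is None:
        raise ValueError("array has no recorded voltages")
    pos = np.asarray(array.positions, dtype=float)
    if len(pos) < 3:
        raise ValueError("CSD needs at least 3 electrodes")
    if not (np.allclose(pos[:, 0], pos[0, 0]) and np.allclose(pos[:, 1], pos[0, 1])):
        raise ValueError("CSD electrodes must lie on a vertical (z) line")
    z = pos[:, 2]
    order = np.argsort(z)
    z = z[order]
    phi = array.voltages[order]
    h = np.diff(z)
    if h.min() <= 0 or (np.abs(h - h[0]) > rtol * abs(h[0])).any():
        raise ValueError("CSD electrodes must be uniformly spaced along z")
    h0 = h[0]
    csd = -array.sigma * (phi[2:] - 2 * phi[1:-1] + phi[:-2]) / h0**2
    return z[1:-1], csd


def spike_histogram(times: Sequence[float], bin_ms: float,
                    t_start: float = 0.0,
                    t_stop: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram event times into half-open bins [t, t + bin).

    Returns (counts, bin_edges).  Counts over [t_start, t_stop) sum to
    the number of events in that window.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    times = np.asarray(times, dtype=float)
    if t_stop is None:
        t_stop = float(times.max()) + bin_ms if times.size else t_start + bin_ms
    n_bins = int(np.ceil((t_stop - t_start) / bin_ms))
    n_bins = max(n_bins, 1)
    edges = t_start + np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins, dtype=int)
    in_range = (times >= t_start) & (times < edges[-1])
    idx = np.floor((times[in_range] - t_start) / bin_ms).astype(int)
    np.add.at(counts, idx, 1)
    return counts, edges
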