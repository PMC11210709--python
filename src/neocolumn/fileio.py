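"""Plain-text readers and writers for dipoles, spikes and target waveforms.

All formats are whitespace/comment text with units stated in the header:
times in ms, dipole moments in nAm, potentials in µV.  Numbers are
written with 6 significant digits; round-trips are exact to that
precision.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

import numpy as np

from .recordings import CellResponse, DipoleRecord


class FileFormatError(ValueError):
    """Malformed row in a text data file; the message cites the line."""


def write_dipole(path, dipole: DipoleRecord) -> None:
    with open(path, "w") as fh:
        fh.write("# neocolumn dipole: time_ms aggregate_nAm L2_nAm L5_nAm\n")
        l2 = dipole.layers.get("L2", np.zeros_like(dipole.aggregate))
        l5 = dipole.layers.get("L5", np.zeros_like(dipole.aggregate))
        for t, a, x2, x5 in zip(dipole.times, dipole.aggregate, l2, l5):
            fh.write(f"{t:.6g} {a:.6g} {x2:.6g} {x5:.6g}\n")


def read_dipole(path) -> DipoleRecord:
    times, agg, l2, l5 = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as err:
                raise FileFormatError(f"{path}: line {lineno}: {err}") from err
            times.append(vals[0])
            agg.append(vals[1])
            l2.append(vals[2])
            l5.append(vals[3])
    if len(times) < 2:
        raise FileFormatError(f"{path}: dipole file needs at least 2 samples")
    return DipoleRecord(times=np.asarray(times),
                        layers={"L2": np.asarray(l2), "L5": np.asarray(l5)},
                        aggregate=np.asarray(agg))


def write_spikes(path, responses: Union[CellResponse, Sequence[CellResponse]]) -> None:
    """Write spikes as (trial, gid, cell_class, time_ms) rows."""
    if isinstance(responses, CellResponse):
        responses = [responses]
    with open(path, "w") as fh:
        fh.write("# neocolumn spikes: trial gid cell_class time_ms\n")
        for trial, resp in enumerate(responses):
            for t, gid in zip(resp.spike_times, resp.spike_gids):
                cls = resp.gid_to_class[int(gid)]
                fh.write(f"{trial} {int(gid)} {cls} {t:.6g}\n")


def read_spikes(path) -> List[CellResponse]:
    """Read spikes back as one CellResponse per trial (empty list if the
    file holds no events)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), parts[2],
                             float(parts[3])))
            except ValueError as err:
                raise FileFormatError(f"{path}: line {lineno}: {err}") from err
    if not rows:
        return []
    n_trials = max(r[0] for r in rows) + 1
    out = []
    for trial in range(n_trials):
        sel = [r for r in rows if r[0] == trial]
        out.append(CellResponse(
            spike_times=np.asarray([r[3] for r in sel]),
            spike_gids=np.asarray([r[1] for r in sel], dtype=int),
            gid_to_class={r[1]: r[2] for r in sel}))
    return out


def read_target_waveform(path) -> Tuple[np.ndarray, np.ndarray]:
    """Two-column text target (time_ms, dipole_nAm); ``#`` comments allowed."""
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as err:
                raise FileFormatError(f"{path}: line {lineno}: {err}") from err
    if len(times) < 2:
        raise FileFormatError(f"{path}: target waveform needs at least 2 samples")
    return np.asarray(times), np.asarray(values)


def write_target_waveform(path, times, values, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# neocolumn target waveform: time_ms dipole_nAm\n")
        if comment:
            fh.write(f"# {comment}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6g} {v:.6g}\n")
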