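"""Exogenous drive event-train generators.

A drive delivers spike events from outside the column onto layer-specific
synaptic targets.  Each targeted cell gets its own independent "drive
unit"; a unit's event train is a pure function of the drive parameters
and a seed, so simulations are reproducible down to the bit.

Kinds
-----
evoked    ``numspikes`` Gaussian-timed events per unit, N(mu, sigma²),
          truncated at 0 ms by resampling (events are causal).
rhythmic  burst centers on a regular 1000/burst_rate ms comb, jittered
          per unit by N(0, sigma²); each burst emits ``numspikes`` events
          at a 10 ms intra-burst spacing, shrunk if needed so a burst
          fits inside one inter-burst interval.
poisson   homogeneous Poisson train at ``rate`` Hz over [t_start, t_stop].
tonic     not an event train: a constant soma current injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

VALID_KINDS = ("evoked", "rhythmic", "poisson", "tonic")
VALID_LOCATIONS = ("proximal", "distal")

#: intra-burst event spacing for rhythmic drives, ms
BURST_SPACING = 10.0


@dataclass
class Drive:
    """One exogenous drive attached to a network.

    ``weights`` maps receptor -> {cell_class: peak conductance µS};
    ``synaptic_delays`` maps cell_class -> ms.  For tonic drives
    ``amplitudes`` maps cell_class -> injected nA and the event-train
    fields are unused.
    """

    name: str
    kind: str
    location: str = "proximal"
    mu: Optional[float] = None  # ms, evoked
    sigma: float = 0.0  # ms: evoked event-time SD / rhythmic burst jitter
    numspikes: int = 1
    burst_rate: Optional[float] = None  # Hz, rhythmic
    rate: Optional[float] = None  # Hz, poisson
    amplitudes: Dict[str, float] = field(default_factory=dict)  # nA, tonic
    t_start: float = 0.0
    t_stop: Optional[float] = None
    weights: Dict[str, Dict[str, float]] = field(default_factory=dict)
    synaptic_delays: Dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None  # explicit seed override
    target_distal_basket: bool = True  # distal drives also reach L2 baskets

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown drive kind {self.kind!r}")
        if self.location not in VALID_LOCATIONS:
            raise ValueError(f"unknown drive location {self.location!r}")
        if self.sigma < 0:
            raise ValueError(f"drive {self.name!r}: sigma must be >= 0")
        if self.numspikes < 1:
            raise ValueError(f"drive {self.name!r}: numspikes must be >= 1")
        if self.kind == "evoked" and self.mu is None:
            raise ValueError(f"drive {self.name!r}: evoked drive requires mu")
        if self.kind == "rhythmic":
            if self.burst_rate is None or self.burst_rate <= 0:
                raise ValueError(f"drive {self.name!r}: burst_rate must be > 0")
            if self.t_stop is None or self.t_stop <= self.t_start:
                raise ValueError(f"drive {self.name!r}: t_stop must exceed t_start")
        if self.kind == "poisson":
            if self.rate is None or self.rate < 0:
                raise ValueError(f"drive {self.name!r}: rate must be >= 0")
            if self.t_stop is None or self.t_stop <= self.t_start:
                raise ValueError(f"drive {self.name!r}: t_stop must exceed t_start")
        for cls in self.targeted_classes():
            if self.kind != "tonic" and cls not in self.synaptic_delays:
                raise ValueError(
                    f"drive {self.name!r}: weighted class {cls!r} has no synaptic delay"
                )

    def targeted_classes(self) -> List[str]:
        if self.kind == "tonic":
            return sorted(self.amplitudes)
        out = set()
        for per_class in self.weights.values():
            out.update(per_class)
        return sorted(out)

    def unit_events(self, rng: np.random.Generator) -> np.ndarray:
        """Event times (ms, sorted) for one drive unit."""
        if self.kind == "evoked":
            return evoked_times(rng, self.mu, self.sigma, self.numspikes)
        if self.kind == "rhythmic":
            return rhythmic_times(rng, self.burst_rate, self.sigma,
                                  self.numspikes, self.t_start, self.t_stop)
        if self.kind == "poisson":
            return poisson_times(rng, self.rate, self.t_start, self.t_stop)
        return np.empty(0)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "location": self.location,
            "mu": self.mu,
            "sigma": self.sigma,
            "numspikes": self.numspikes,
            "burst_rate": self.burst_rate,
            "rate": self.rate,
            "amplitudes": dict(self.amplitudes),
            "t_start": self.t_start,
            "t_stop": self.t_stop,
            "weights": {r: dict(w) for r, w in self.weights.items()},
            "synaptic_delays": dict(self.synaptic_delays),
            "seed": self.seed,
            "target_distal_basket": self.target_distal_basket,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Drive":
        return cls(**d)


def evoked_times(rng: np.random.Generator, mu: float, sigma: float,
                 numspikes: int) -> np.ndarray:
    """``numspikes`` draws from N(mu, sigma²) truncated at 0 by resampling."""
    if sigma == 0:
        return np.full(numspikes, float(mu))
    t = rng.normal(mu, sigma, size=numspikes)
    while np.any(t < 0):
        bad = t < 0
        t[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
    return np.sort(t)


def rhythmic_times(rng: np.random.Generator, burst_rate: float, sigma: float,
                   numspikes: int, t_start: float, t_stop: float) -> np.ndarray:
    """Jittered burst train; see module docstring for the generator."""
    interval = 1000.0 / burst_rate
    n_bursts = int(np.floor((t_stop - t_start) / interval - 1e-12)) + 1
    centers = t_start + np.arange(n_bursts) * interval
    if sigma > 0:
        centers = centers + rng.normal(0.0, sigma, size=n_bursts)
    spacing = min(BURST_SPACING, interval / numspikes)
    offsets = (np.arange(numspikes) - (numspikes - 1) / 2.0) * spacing
    events = (centers[:, None] + offsets[None, :]).ravel()
    events = events[(events >= 0) & (events <= t_stop)]
    return np.sort(events)


def poisson_times(rng: np.random.Generator, rate: float, t_start: float,
                  t_stop: float) -> np.ndarray:
    """Homogeneous Poisson event train at ``rate`` Hz over [t_start, t_stop]."""
    if rate == 0:
        return np.empty(0)
    duration_s = (t_stop - t_start) / 1000.0
    n = rng.poisson(rate * duration_s)
    return np.sort(rng.uniform(t_start, t_stop, size=n))


def drive_seed(master_seed: int, trial: int, drive_index: int,
               override: Optional[int] = None) -> int:
    """Seed for drive ``drive_index`` on trial ``trial``.

    master + 1000*trial + index, so trials are independent and each
    drive has its own stream.  Kept below 2**31.
    """
    base = override if override is not None else master_seed + drive_index
    return int(base + 1000 * trial) % (2**31)


def sample_drive_units(drive: Drive, n_units: int, master_seed: int,
                       trial: int = 0, drive_index: int = 0) -> List[np.ndarray]:
    """Event trains for ``n_units`` independent drive units (one per
    targeted cell), drawn sequentially from a single seeded stream."""
    rng = np.random.default_rng(
        drive_seed(master_seed, trial, drive_index, drive.seed))
    return [drive.unit_events(rng) for _ in range(n_units)]
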