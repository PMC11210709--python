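"""Built-in example configurations and synthetic targets.

These are the workflow entry points the tool documents: the brief
"feedforward" proximal evoked input (evprox1) and the alpha-rhythm
workflow (proximal + distal jittered 10 Hz burst drives).  The ERP
target generator makes a purely synthetic evoked-like waveform for
exercising the RMSE/optimization loop without any recorded data.
"""

from __future__ import annotations

import numpy as np

from .config import (BuilderConfig, ConfigDocument, DriveConfig, NetworkConfig,
                     SimulationConfig)
from .network import Network, default_network

# weights (peak µS) and delays (ms) of the evprox1 example drive
EVPROX1_WEIGHTS_AMPA = {
    "L2_basket": 0.09,
    "L2_pyramidal": 0.02,
    "L5_basket": 0.2,
    "L5_pyramidal": 8e-3,
}
EVPROX1_DELAYS = {
    "L2_basket": 0.1,
    "L2_pyramidal": 0.1,
    "L5_basket": 1.0,
    "L5_pyramidal": 1.0,
}
EVPROX1_MU = 20.0
EVPROX1_SIGMA = 2.0
EVPROX1_NUMSPIKES = 1

# alpha workflow: weak subthreshold burst drives at the alpha rate
ALPHA_BURST_RATE = 10.0  # bursts/s
ALPHA_SIGMA = 20.0  # ms burst jitter
ALPHA_NUMSPIKES = 2
ALPHA_WEIGHTS_AMPA = {"L2_pyramidal": 3e-3, "L5_pyramidal": 3e-3}
ALPHA_DELAYS = {"L2_pyramidal": 0.1, "L5_pyramidal": 1.0}
ALPHA_TSTOP = 2000.0  # ms


def evprox1_network(grid_shape=(10, 10), n_basket=35) -> Network:
    """Default column with the evprox1 proximal evoked drive attached."""
    net = default_network(grid_shape=grid_shape, n_basket=n_basket)
    net.add_evoked_drive(
        name="evprox1", mu=EVPROX1_MU, sigma=EVPROX1_SIGMA,
        numspikes=EVPROX1_NUMSPIKES, location="proximal",
        weights_ampa=dict(EVPROX1_WEIGHTS_AMPA),
        synaptic_delays=dict(EVPROX1_DELAYS))
    return net


def evprox1_config(tstop: float = 100.0) -> ConfigDocument:
    return ConfigDocument(
        network=NetworkConfig(
            builder=BuilderConfig(),
            drives=[DriveConfig(
                name="evprox1", kind="evoked", location="proximal",
                mu=EVPROX1_MU, sigma=EVPROX1_SIGMA, numspikes=EVPROX1_NUMSPIKES,
                weights={"ampa": dict(EVPROX1_WEIGHTS_AMPA)},
                synaptic_delays=dict(EVPROX1_DELAYS))]),
        simulation=SimulationConfig(tstop=tstop),
    )


def alpha_network(grid_shape=(10, 10), n_basket=35,
                  t_stop: float = ALPHA_TSTOP) -> Network:
    """Default column with proximal + distal 10 Hz jittered-burst drives.

    Both drives share the burst rate but have independent jitter, the
    standard recipe for an alpha-band dipole rhythm.
    """
    net = default_network(grid_shape=grid_shape, n_basket=n_basket)
    for name, location in (("alpha_prox", "proximal"), ("alpha_dist", "distal")):
        net.add_rhythmic_drive(
            name=name, burst_rate=ALPHA_BURST_RATE, sigma=ALPHA_SIGMA,
            numspikes=ALPHA_NUMSPIKES, t_start=50.0, t_stop=t_stop,
            location=location, weights_ampa=dict(ALPHA_WEIGHTS_AMPA),
            synaptic_delays=dict(ALPHA_DELAYS), target_distal_basket=False)
    return net


def alpha_config(tstop: float = ALPHA_TSTOP) -> ConfigDocument:
    drives = []
    for name, location in (("alpha_prox", "proximal"), ("alpha_dist", "distal")):
        drives.append(DriveConfig(
            name=name, kind="rhythmic", location=location,
            burst_rate=ALPHA_BURST_RATE, sigma=ALPHA_SIGMA,
            numspikes=ALPHA_NUMSPIKES, t_start=50.0, t_stop=tstop,
            weights={"ampa": dict(ALPHA_WEIGHTS_AMPA)},
            synaptic_delays=dict(ALPHA_DELAYS), target_distal_basket=False))
    return ConfigDocument(
        network=NetworkConfig(builder=BuilderConfig(), drives=drives),
        simulation=SimulationConfig(tstop=tstop),
    )


def synthetic_erp_target(tstop: float = 100.0, dt: float = 0.1,
                         peak_time: float = 30.0, peak_amp: float = 0.05,
                         trough_time: float = 55.0, trough_amp: float = -0.03):
    """Synthetic evoked-like target waveform (sum of two Gaussians), nAm.

    Purely synthetic: stands in for a source-localised ERP waveform when
    exercising the fitting workflow.  Returns (times, values).
    """
    t = np.arange(0.0, tstop + dt / 2, dt)
    wave = (peak_amp * np.exp(-((t - peak_time) ** 2) / (2 * 6.0**2))
            + trough_amp * np.exp(-((t - trough_time) ** 2) / (2 * 10.0**2)))
    return t, wave
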