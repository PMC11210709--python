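"""Integrator accuracy, determinism and event-delivery contracts."""

import numpy as np
import pytest

from neocolumn.engine import SimulationSettings, SimulationState, simulate, step
from neocolumn.network import Network, Population, default_network
from neocolumn.recordings import compute_dipole

from conftest import driven_small_column, passive_point_network


def test_settings_validation():
    with pytest.raises(ValueError):
        SimulationSettings(tstop=-1.0)
    with pytest.raises(ValueError):
        SimulationSettings(tstop=100.0, dt=0.5)
    with pytest.raises(ValueError):
        SimulationSettings(tstop=100.0, n_trials=0)


def test_leak_decay_matches_closed_form():
    """A displaced passive compartment relaxes as v_rest + 10·exp(-t/τ),
    τ = C/g; backward Euler at dt = 0.025 ms stays within 0.5%."""
    net = passive_point_network(gbar=0.05)  # τ = 1/0.05 = 20 ms
    state = SimulationState(net, SimulationSettings(tstop=60.0, dt=0.025))
    state.groups[0].v[:] = -55.0
    tau = 1.0 / 0.05
    ts, vs = [0.0], [-55.0]
    for _ in range(state.n_steps):
        step(state)
        ts.append(state.t)
        vs.append(float(state.groups[0].v[0, 0]))
    expected = -65.0 + 10.0 * np.exp(-np.asarray(ts) / tau)
    err = np.abs(np.asarray(vs) - expected) / 10.0
    assert err.max() < 0.005


def test_zero_conductance_compartment_holds_voltage():
    net = passive_point_network(gbar=0.05)
    net.templates["L5_basket"].mechanisms["soma"][0].gbar = 0.0
    state = SimulationState(net, SimulationSettings(tstop=10.0))
    state.groups[0].v[:] = -50.0
    for _ in range(state.n_steps):
        step(state)
    assert np.isclose(state.groups[0].v[0, 0], -50.0, atol=1e-12)


def test_dt_halving_converges(single_l5_network):
    """Self-consistency: a subthreshold driven voltage trace changes little
    when dt is halved."""
    traces = {}
    for dt in (0.05, 0.025):
        net = single_l5_network.copy()
        net.add_evoked_drive(name="weak", mu=10.0, sigma=0.0, numspikes=1,
                             location="proximal",
                             weights_ampa={"L5_pyramidal": 5e-4},
                             synaptic_delays={"L5_pyramidal": 1.0})
        settings = SimulationSettings(tstop=100.0, dt=dt, record_voltages=True)
        raw = simulate(net, settings)[0]
        stride = int(round(0.1 / dt))
        traces[dt] = raw.voltages["L5_pyramidal"][::stride, 0, 0]
    diff = np.abs(traces[0.05] - traces[0.025]).max()
    assert diff < 0.5  # mV


def test_resting_default_column_is_silent():
    """No drives → no spikes over 100 ms in the full default column."""
    net = default_network()
    raw = simulate(net, SimulationSettings(tstop=100.0))[0]
    assert raw.spike_times.size == 0
    dip = compute_dipole(raw)
    assert np.abs(dip.aggregate).max() < 1e-12


def test_same_seed_bit_identical():
    settings = SimulationSettings(tstop=60.0, master_seed=3)
    a = simulate(driven_small_column(), settings)[0]
    b = simulate(driven_small_column(), settings)[0]
    np.testing.assert_array_equal(a.spike_times, b.spike_times)
    np.testing.assert_array_equal(a.spike_gids, b.spike_gids)
    np.testing.assert_array_equal(a.dipole_layers["L5"], b.dipole_layers["L5"])


def test_trials_use_distinct_drive_seeds():
    net = driven_small_column()
    raws = simulate(net, SimulationSettings(tstop=40.0, n_trials=3,
                                            master_seed=0))
    assert [r.trial for r in raws] == [0, 1, 2]
    trains = [np.concatenate(r.drive_events["evprox1"]) for r in raws]
    assert not np.array_equal(trains[0], trains[1])
    assert not np.array_equal(trains[1], trains[2])


def test_trial_map_hook_matches_serial():
    net = driven_small_column()
    settings = SimulationSettings(tstop=40.0, n_trials=2, master_seed=1)
    serial = simulate(net, settings)
    mapped = simulate(net, settings, trial_map=lambda f, xs: reversed(
        [f(x) for x in reversed(list(xs))]))
    for a, b in zip(serial, mapped):
        assert a.trial == b.trial
        np.testing.assert_array_equal(a.spike_times, b.spike_times)


def test_event_delay_respected(single_l5_network):
    """An event emitted at mu with synaptic delay d cannot move the
    membrane before mu + d."""
    net = single_l5_network
    net.add_evoked_drive(name="late", mu=20.0, sigma=0.0, numspikes=1,
                         location="proximal",
                         weights_ampa={"L5_pyramidal": 0.01},
                         synaptic_delays={"L5_pyramidal": 5.0})
    raw = simulate(net, SimulationSettings(tstop=40.0, record_voltages=True))[0]
    v = raw.voltages["L5_pyramidal"][:, 0, :]
    before = raw.times <= 25.0
    assert np.abs(v[before] - (-65.0)).max() < 1e-9
    assert np.abs(v[~before] - (-65.0)).max() > 0.1


def test_membrane_currents_conserve_charge():
    """Summed compartment membrane currents of an isolated cell equal the
    injected current (Kirchhoff on the cell's tree)."""
    net = Network([Population("L5_pyramidal", [(0.0, 0.0, 0.0)])])
    net.add_tonic_bias("inj", amplitudes={"L5_pyramidal": 0.3},
                       t_start=10.0, t_stop=100.0)
    raw = simulate(net, SimulationSettings(tstop=100.0), record_currents=True)[0]
    total = raw.tm_currents["L5_pyramidal"].sum(axis=2)[:, 0]  # nA
    injected = np.where((raw.times >= 10.0) & (raw.times <= 100.0), 0.3, 0.0)
    np.testing.assert_allclose(total, injected, atol=1e-9)
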