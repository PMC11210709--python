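"""Dipole bookkeeping, extracellular potentials, CSD and spike histograms."""

import numpy as np
import pytest

from neocolumn.engine import SimulationSettings, simulate
from neocolumn.network import Network, Population
from neocolumn.recordings import (
    ExtracellularArray,
    cell_response,
    compute_csd,
    compute_dipole,
    compute_lfp,
    dipole_from_axial,
    point_source_transfer,
    spike_histogram,
)
from neocolumn.drives import Drive, sample_drive_units

from conftest import driven_small_column

SIGMA = 0.3  # S/m


def _driven_single_l5(weight=8e-3, tstop=60.0, **kw):
    net = Network([Population("L5_pyramidal", [(0.0, 0.0, 0.0)])])
    net.add_evoked_drive(name="ev", mu=20.0, sigma=0.0, numspikes=1,
                         location="proximal",
                         weights_ampa={"L5_pyramidal": weight},
                         synaptic_delays={"L5_pyramidal": 1.0})
    raw = simulate(net, SimulationSettings(tstop=tstop), **kw)[0]
    return raw


class TestDipole:
    def test_layer_decomposition_identity(self):
        raw = simulate(driven_small_column(),
                       SimulationSettings(tstop=60.0, master_seed=2))[0]
        dpl = compute_dipole(raw)
        np.testing.assert_allclose(
            dpl.aggregate, dpl.layers["L2"] + dpl.layers["L5"],
            rtol=0, atol=1e-15)

    def test_toy_pair_is_current_times_separation(self):
        # constant 2 nA across 300 µm of vertical separation
        p = dipole_from_axial(np.array([2.0]), np.array([300.0]))
        assert np.isclose(p, 2.0 * 300.0 * 1e-6)  # nAm

    def test_dipole_operator_is_linear(self):
        rng = np.random.default_rng(0)
        i1 = rng.normal(size=(50, 6))
        i2 = rng.normal(size=(50, 6))
        dz = rng.uniform(50, 300, size=6)
        np.testing.assert_allclose(
            dipole_from_axial(i1 + i2, dz),
            dipole_from_axial(i1, dz) + dipole_from_axial(i2, dz), rtol=1e-12)

    def test_proximal_drive_deflects_positive(self):
        """Proximal excitation pushes current up the apical dendrites:
        the initial aggregate deflection is positive by the deep-to-
        superficial sign convention."""
        raw = _driven_single_l5(weight=1e-3)
        dpl = compute_dipole(raw)
        onset = np.argmax(np.abs(dpl.aggregate) > 1e-7)
        window = dpl.aggregate[onset:onset + 200]
        assert window.max() > 0
        assert abs(window.max()) > abs(window.min())

    def test_smoothing_and_scaling_keep_raw(self):
        raw = _driven_single_l5()
        dpl = compute_dipole(raw)
        sm = dpl.smooth().scale(3000.0)
        assert sm.raw is dpl
        np.testing.assert_allclose(
            sm.aggregate, sm.layers["L2"] + sm.layers["L5"], atol=1e-15)
        assert sm.scaling == 3000.0
        # original untouched
        assert dpl.scaling == 1.0 and dpl.smoothing_window_ms == 0.0


class TestLFP:
    def test_point_source_formula(self):
        # 1 nA at 1 mm in sigma = 0.3 S/m: φ = 1e-3 / (4π·0.3·1e-3) µV
        m = point_source_transfer(np.array([[1000.0, 0, 0]]),
                                  np.array([[0.0, 0, 0]]), SIGMA)
        expected = 1e-3 / (4 * np.pi * SIGMA * 1e-3)
        assert np.isclose(m[0, 0], expected)

    def test_inverse_distance_decay(self):
        m = point_source_transfer(np.array([[500.0, 0, 0], [1000.0, 0, 0]]),
                                  np.array([[0.0, 0, 0]]), SIGMA)
        assert np.isclose(m[0, 0] / m[1, 0], 2.0)

    def test_electrode_inside_compartment_rejected(self):
        raw = _driven_single_l5(record_currents=True, tstop=2.0)
        arr = ExtracellularArray(positions=[(0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="inside"):
            compute_lfp(raw, arr)

    def test_whole_cell_field_decays_faster_than_monopole(self):
        """An isolated cell's membrane currents sum to ~0, so the far
        field falls off faster than 1/r."""
        raw = _driven_single_l5(record_currents=True)
        near = compute_lfp(raw, ExtracellularArray(positions=[(2000.0, 0, 500.0)]))
        far = compute_lfp(raw, ExtracellularArray(positions=[(20000.0, 0, 500.0)]))
        peak_near = np.abs(near.voltages).max()
        peak_far = np.abs(far.voltages).max()
        assert peak_far < 0.02 * peak_near  # monopole would give 0.1

    def test_lfp_and_dipole_timing_consistent(self):
        """Peak |dφ| and peak |d(dipole)/dt| of the same driven cell fall
        within one synaptic time constant of each other."""
        raw = _driven_single_l5(record_currents=True)
        dpl = compute_dipole(raw)
        lfp = compute_lfp(raw, ExtracellularArray(positions=[(500.0, 0, 300.0)]))
        t_lfp = raw.times[np.argmax(np.abs(lfp.voltages[0]))]
        slope = np.gradient(dpl.aggregate, dpl.times)
        t_dip = raw.times[np.argmax(np.abs(slope))]
        assert abs(t_lfp - t_dip) <= 5.0  # ms, AMPA decay constant


class TestCSD:
    def _array(self, phi_per_z, z):
        elec = [(0.0, 0.0, float(zi)) for zi in z]
        v = np.asarray(phi_per_z, dtype=float)[:, None]
        return ExtracellularArray(positions=elec, voltages=v,
                                  times=np.array([0.0]))

    def test_linear_potential_gives_zero(self):
        z = np.arange(0, 500, 50.0)
        _, csd = compute_csd(self._array(3.0 * z + 7.0, z))
        np.testing.assert_allclose(csd, 0.0, atol=1e-12)

    def test_quadratic_potential_gives_minus_two_sigma(self):
        z = np.arange(0, 500, 50.0)
        _, csd = compute_csd(self._array(z**2, z))
        np.testing.assert_allclose(csd, -2.0 * SIGMA, rtol=1e-9)

    def test_quadrupole_sink_source_sink(self):
        src = np.array([[0, 0, -100.0], [0, 0, 0.0], [0, 0, 100.0]])
        currents = np.array([-1.0, 2.0, -1.0])  # sinks flanking a source
        z = np.arange(-200, 201, 25.0)
        elec = np.column_stack([np.full_like(z, 50.0), np.zeros_like(z), z])
        phi = point_source_transfer(elec, src, SIGMA) @ currents
        arr = ExtracellularArray(positions=[tuple(p) for p in elec],
                                 voltages=phi[:, None], times=np.array([0.0]))
        depths, csd = compute_csd(arr)
        prof = csd[:, 0]
        assert prof[depths == 0.0][0] > 0  # source at the center
        assert prof[depths == -100.0][0] < 0
        assert prof[depths == 100.0][0] < 0

    def test_nonuniform_spacing_rejected(self):
        arr = self._array([0.0, 1.0, 4.0, 9.0], [0.0, 50.0, 120.0, 150.0])
        with pytest.raises(ValueError, match="uniform"):
            compute_csd(arr)

    def test_fewer_than_three_electrodes_rejected(self):
        arr = self._array([0.0, 1.0], [0.0, 50.0])
        with pytest.raises(ValueError, match="3 electrodes"):
            compute_csd(arr)


class TestSpikeHistogram:
    def test_empty_input_all_zero(self):
        counts, edges = spike_histogram([], 5.0, t_start=0.0, t_stop=50.0)
        assert counts.sum() == 0
        assert len(counts) == 10

    def test_half_open_bin_convention(self):
        counts, edges = spike_histogram([0.0, 5.0, 9.999, 10.0], 5.0,
                                        t_start=0.0, t_stop=15.0)
        np.testing.assert_array_equal(counts, [1, 2, 1])

    def test_counts_sum_to_events(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 100, size=500)
        counts, _ = spike_histogram(times, 7.0, t_start=0.0, t_stop=105.0)
        assert counts.sum() == 500

    def test_evoked_drive_histogram_mode_near_mu(self):
        drive = Drive(name="ev", kind="evoked", mu=20.0, sigma=2.0, numspikes=1,
                      weights={"ampa": {"L5_pyramidal": 0.01}},
                      synaptic_delays={"L5_pyramidal": 0.1})
        events = np.concatenate(sample_drive_units(drive, 10_000, master_seed=0))
        counts, edges = spike_histogram(events, 1.0, t_start=0.0, t_stop=40.0)
        mode_bin = edges[np.argmax(counts)]
        assert 18.0 <= mode_bin <= 22.0


def test_cell_response_partitions_by_class():
    raw = simulate(driven_small_column(),
                   SimulationSettings(tstop=60.0, master_seed=0))[0]
    resp = cell_response(raw)
    assert raw.spike_times.size > 0
    n_by_class = sum(resp.times_for_class(cls).size
                     for cls in ("L2_basket", "L2_pyramidal",
                                 "L5_basket", "L5_pyramidal"))
    assert n_by_class == raw.spike_times.size
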