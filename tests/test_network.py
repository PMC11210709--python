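"""Network assembly, default column composition, drives and connectivity."""

import numpy as np
import pytest

from neocolumn.cells import TemplateValidationError
from neocolumn.drives import Drive, poisson_times, rhythmic_times, sample_drive_units
from neocolumn.engine import SimulationSettings, SimulationState, simulate
from neocolumn.network import ConnectionRule, default_network
from neocolumn.recordings import compute_dipole

from conftest import driven_small_column, passive_point_network


class TestDefaultColumn:
    def test_composition_matches_canonical_counts(self):
        net = default_network()
        assert net.population("L2_pyramidal").count == 100
        assert net.population("L5_pyramidal").count == 100
        assert net.population("L2_basket").count == 35
        assert net.population("L5_basket").count == 35
        assert net.n_cells == 270

    def test_positions_unique_and_layered(self):
        net = default_network()
        for pop in net.populations:
            pop.validate()
        z2 = {p[2] for p in net.population("L2_pyramidal").positions}
        z5 = {p[2] for p in net.population("L5_pyramidal").positions}
        assert min(z2) > max(z5)  # L2/3 sits above L5

    def test_each_layer_has_pyramidal_basket_loop(self):
        net = default_network()
        pairs = {(r.src_class, r.dst_class) for r in net.connectivity}
        for layer in ("L2", "L5"):
            assert (f"{layer}_pyramidal", f"{layer}_basket") in pairs
            assert (f"{layer}_basket", f"{layer}_pyramidal") in pairs
        assert ("L2_pyramidal", "L5_pyramidal") in pairs


class TestEvokedDrive:
    def test_event_time_moments(self):
        drive = Drive(name="ev", kind="evoked", mu=20.0, sigma=2.0,
                      numspikes=1, weights={"ampa": {"L5_pyramidal": 0.01}},
                      synaptic_delays={"L5_pyramidal": 0.1})
        events = np.concatenate(sample_drive_units(drive, 10_000, master_seed=42))
        sem = 2.0 / np.sqrt(events.size)
        assert abs(events.mean() - 20.0) < 3 * sem
        sd_sem = 2.0 / np.sqrt(2 * (events.size - 1))
        assert abs(events.std(ddof=1) - 2.0) < 3 * sd_sem

    def test_zero_sigma_is_degenerate(self):
        drive = Drive(name="ev", kind="evoked", mu=17.5, sigma=0.0, numspikes=4,
                      weights={"ampa": {"L5_pyramidal": 0.01}},
                      synaptic_delays={"L5_pyramidal": 0.1})
        for unit in sample_drive_units(drive, 5, master_seed=0):
            assert unit.shape == (4,)
            assert np.all(unit == 17.5)

    def test_events_are_causal(self):
        drive = Drive(name="ev", kind="evoked", mu=1.0, sigma=5.0, numspikes=2,
                      weights={"ampa": {"L5_pyramidal": 0.01}},
                      synaptic_delays={"L5_pyramidal": 0.1})
        events = np.concatenate(sample_drive_units(drive, 2000, master_seed=3))
        assert events.min() >= 0.0

    def test_negative_sigma_rejected(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        with pytest.raises(ValueError, match="sigma"):
            net.add_evoked_drive(name="bad", mu=20.0, sigma=-1.0, numspikes=1,
                                 weights_ampa={"L5_pyramidal": 0.01},
                                 synaptic_delays={"L5_pyramidal": 0.1})

    def test_duplicate_drive_name_rejected(self):
        net = driven_small_column()
        with pytest.raises(ValueError, match="duplicate"):
            net.add_evoked_drive(name="evprox1", mu=30.0, sigma=1.0, numspikes=1,
                                 weights_ampa={"L5_pyramidal": 0.01},
                                 synaptic_delays={"L5_pyramidal": 0.1})

    def test_missing_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            Drive(name="ev", kind="evoked", mu=10.0,
                  weights={"ampa": {"L5_pyramidal": 0.01}}, synaptic_delays={})


class TestRhythmicDrive:
    def test_deterministic_burst_comb(self):
        rng = np.random.default_rng(0)
        events = rhythmic_times(rng, burst_rate=10.0, sigma=0.0, numspikes=1,
                                t_start=50.0, t_stop=1050.0)
        np.testing.assert_allclose(events, 50.0 + 100.0 * np.arange(10))

    def test_mean_interburst_interval(self):
        """Monte-Carlo mean interval at 10 bursts/s with 10 ms jitter."""
        intervals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ev = rhythmic_times(rng, burst_rate=10.0, sigma=10.0, numspikes=1,
                                t_start=50.0, t_stop=2050.0)
            intervals.append(np.diff(ev))
        intervals = np.concatenate(intervals)
        assert abs(intervals.mean() - 100.0) < 2.0

    def test_numspikes_per_burst(self):
        rng = np.random.default_rng(0)
        events = rhythmic_times(rng, burst_rate=10.0, sigma=0.0, numspikes=2,
                                t_start=100.0, t_stop=1000.0)
        assert events.size == 2 * 9
        gaps = np.diff(events)[::2]
        np.testing.assert_allclose(gaps, 10.0)  # intra-burst spacing

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="t_stop"):
            Drive(name="r", kind="rhythmic", burst_rate=10.0, t_start=100.0,
                  t_stop=50.0, weights={"ampa": {"L5_pyramidal": 0.01}},
                  synaptic_delays={"L5_pyramidal": 0.1})


class TestPoissonDrive:
    def test_zero_rate_no_events(self):
        rng = np.random.default_rng(0)
        assert poisson_times(rng, 0.0, 0.0, 1000.0).size == 0

    def test_mean_count(self):
        rng = np.random.default_rng(7)
        counts = [poisson_times(rng, 100.0, 0.0, 1000.0).size
                  for _ in range(1000)]
        sem = np.sqrt(100.0) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 100.0) < 3 * sem

    def test_interval_cv_is_poisson_like(self):
        rng = np.random.default_rng(11)
        isi = np.concatenate([np.diff(poisson_times(rng, 50.0, 0.0, 10_000.0))
                              for _ in range(20)])
        cv = isi.std() / isi.mean()
        assert abs(cv - 1.0) < 0.05

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            Drive(name="p", kind="poisson", rate=-5.0, t_stop=100.0,
                  weights={"ampa": {"L5_pyramidal": 0.01}},
                  synaptic_delays={"L5_pyramidal": 0.1})


class TestConnectivity:
    def test_uniform_rule_weights(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        rule = ConnectionRule("L2_pyramidal", "L5_pyramidal", "ampa",
                              "proximal", weight=0.01, delay=1.0)
        w = net.pair_weights(rule)
        assert np.all(w == 0.01)

    def test_gaussian_falloff_at_lambda(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        rule = ConnectionRule("L2_pyramidal", "L5_pyramidal", "ampa",
                              "proximal", weight=0.01, delay=1.0,
                              space_constant=100.0)
        w = net.pair_weights(rule)
        # grid spacing is 100 µm: nearest inter-cell distance equals λ
        src = np.asarray(net.population("L2_pyramidal").positions)[:, :2]
        dst = np.asarray(net.population("L5_pyramidal").positions)[:, :2]
        d = np.linalg.norm(src[0] - dst[1])
        assert np.isclose(d, 100.0)
        assert np.isclose(w[0, 1], 0.01 * np.exp(-1.0))

    def test_autapses_removed(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        rule = ConnectionRule("L5_pyramidal", "L5_pyramidal", "ampa",
                              "proximal", weight=0.01, delay=1.0)
        assert np.all(np.diag(net.pair_weights(rule)) == 0)

    def test_zero_weight_rule_is_null(self):
        settings = SimulationSettings(tstop=40.0, master_seed=1)
        base = driven_small_column()
        dip_a = compute_dipole(simulate(base, settings)[0])
        with_null = driven_small_column()
        with_null.connect(ConnectionRule("L5_pyramidal", "L2_pyramidal",
                                         "ampa", "distal", weight=0.0, delay=1.0))
        dip_b = compute_dipole(simulate(with_null, settings)[0])
        np.testing.assert_array_equal(dip_a.aggregate, dip_b.aggregate)

    def test_unknown_receptor_rejected(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        with pytest.raises(ValueError, match="receptor"):
            net.connect(ConnectionRule("L5_pyramidal", "L2_pyramidal",
                                       "glycine", "soma", weight=0.01, delay=1.0))


class TestDriveTargeting:
    def test_proximal_never_reaches_distal_compartments(self):
        """Site-targeting exclusivity, checked on the scheduled conductance
        increments themselves."""
        net = driven_small_column()
        state = SimulationState(net, SimulationSettings(tstop=60.0))
        tpl = net.templates["L5_pyramidal"]
        gi = state.group_index["L5_pyramidal"]
        distal = {tpl.comp_names.index(n) for n in tpl.synapse_sites["distal"]}
        proximal = {tpl.comp_names.index(n) for n in tpl.synapse_sites["proximal"]}
        touched = set()
        for bucket in state.buckets.values():
            for (g, _rec), chunks in bucket.items.items():
                if g != gi:
                    continue
                for _cells, comps, _w in chunks:
                    touched.update(int(c) for c in comps)
        assert touched  # the drive does reach L5 pyramidal cells
        assert touched <= proximal
        assert not (touched & distal)

    def test_drive_event_trains_seed_pure(self):
        drive = Drive(name="ev", kind="evoked", mu=20.0, sigma=2.0, numspikes=2,
                      weights={"ampa": {"L5_pyramidal": 0.01}},
                      synaptic_delays={"L5_pyramidal": 0.1})
        a = sample_drive_units(drive, 10, master_seed=5)
        b = sample_drive_units(drive, 10, master_seed=5)
        c = sample_drive_units(drive, 10, master_seed=6)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


class TestModifyCell:
    def test_identity_patch_keeps_template(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        before = net.templates["L2_pyramidal"].to_dict()
        net.modify_cell("L2_pyramidal", {})
        assert net.templates["L2_pyramidal"].to_dict() == before

    def test_invalid_synapse_patch_rejected_with_field(self):
        net = default_network(grid_shape=(3, 3), n_basket=3)
        with pytest.raises(TemplateValidationError, match="tau_rise"):
            net.modify_cell("L2_pyramidal",
                            {"synapses": {"ampa": {"tau_rise": 10.0,
                                                   "tau_decay": 1.0}}})

    def test_doubling_leak_halves_time_constant(self):
        """Passive step response: τ = C / g_leak, so 2× leak → τ/2."""
        taus = {}
        for gbar in (0.05, 0.1):
            net = passive_point_network(gbar=gbar)
            net.add_tonic_bias("step", amplitudes={"L5_basket": 0.05},
                               t_start=10.0, t_stop=200.0)
            settings = SimulationSettings(tstop=120.0, record_voltages=True)
            raw = simulate(net, settings)[0]
            v = raw.voltages["L5_basket"][:, 0, 0]
            t = raw.times
            v_inf = v[-1]
            target = -65.0 + (1 - np.exp(-1.0)) * (v_inf + 65.0)
            taus[gbar] = t[np.argmax(v >= target)] - 10.0
        assert np.isclose(taus[0.1] / taus[0.05], 0.5, rtol=0.02)
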