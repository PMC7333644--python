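"""Network construction and simulation engine."""

import math

import numpy as np
import pytest

from hexcpg import (
    LEGS,
    HexapodSpec,
    Network,
    NoiseSpec,
    PopulationSpec,
    Simulator,
    SpikeRaster,
    SynapseSpec,
    alpha_conductance,
    build_hexapod,
    build_leg,
    build_scpg,
    cpg_parameters,
    detect_bursts,
    run_network,
    run_segments,
)
from hexcpg.cpg_network import TopologyError
from hexcpg.modulation import ScheduleSegment


def single_neuron_network(V_T=-56.0, noise_std=0.0):
    net = Network()
    net.add_population(
        PopulationSpec("n", 1, cpg_parameters(V_T), NoiseSpec(std=noise_std))
    )
    return net


def reference_spike_count(duration_ms, dt, V_T=-56.0):
    """Independent fine-step forward-Euler integration of the same hybrid
    system (single neuron, no input): the convergence oracle."""
    C, gL, EL, DT, tw = 200.0, 10.0, -58.0, 2.0, 120.0
    a, b, Vr, Ie, tref, Vpk = 2.0, 100.0, -46.0, 500.0, 2.0, 0.0
    V, w, ref, n = EL, 0.0, 0.0, 0
    for _ in range(int(round(duration_ms / dt))):
        if ref > 0:
            w += dt * (a * (Vr - EL) - w) / tw
            ref = max(0.0, ref - dt)
            continue
        arg = min((V - V_T) / DT, 20.0)
        dV = (-gL * (V - EL) + gL * DT * math.exp(arg) - w + Ie) / C
        dw = (a * (V - EL) - w) / tw
        V += dt * dV
        w += dt * dw
        if V >= Vpk:
            V, w, ref, n = Vr, w + b, tref, n + 1
    return n


class TestBuilders:
    def test_minimal_half_center(self):
        net = build_scpg(cpg_parameters(-56.0), size=1, mutual_weight=-10.0)
        assert net.n_neurons == 2
        assert len(net.connections) == 2
        assert all(c.synapse.weight < 0 for c in net.connections)

    def test_five_neuron_half_center_synapse_count(self):
        net = build_scpg(cpg_parameters(-56.0), size=5)
        # 2 population-level projections, each all-to-all 5x5
        pairs = sum(
            net.populations[c.source].size * net.populations[c.target].size
            for c in net.connections
        )
        assert net.n_neurons == 10
        assert pairs == 50

    def test_half_center_requires_inhibition(self):
        with pytest.raises(TopologyError):
            build_scpg(cpg_parameters(-56.0), mutual_weight=10.0)

    def test_leg_population_and_neuron_counts(self):
        net = build_leg("FL", cpg_parameters(-56.0))
        assert len(net.populations) == 6
        assert net.n_neurons == 30
        assert set(net.motor_labels()) == {"FL.TC.motor", "FL.CF.motor"}

    def test_leg_cf_motor_edge_carries_delay(self):
        net = build_leg("FL", cpg_parameters(-56.0), cf_delay=250.0)
        cf_edges = [c for c in net.connections if c.tag == "motor.cf"]
        assert len(cf_edges) == 1 and cf_edges[0].synapse.delay == 250.0
        tc_edges = [c for c in net.connections if c.tag == "motor.tc"]
        assert len(tc_edges) == 1 and tc_edges[0].synapse.delay == pytest.approx(0.1)

    def test_leg_weight_signs_enforced(self):
        with pytest.raises(TopologyError):
            build_leg("FL", cpg_parameters(-56.0), joint_weight=1.0)
        with pytest.raises(TopologyError):
            build_leg("FL", cpg_parameters(-56.0), motor_weight=-1.0)

    def test_motor_populations_have_no_bias_current(self):
        net = build_leg("FL", cpg_parameters(-56.0))
        assert net.populations["FL.TC.motor"].params.I_e == 0.0
        assert net.populations["FL.TC.1"].params.I_e == 500.0

    @pytest.mark.parametrize("mode,per_pair", [("full", 8), ("first_only", 4)])
    def test_hexapod_counts(self, mode, per_pair):
        net = build_hexapod(HexapodSpec(coupling_mode=mode))
        assert len(net.populations) == 36
        assert net.n_neurons == 180
        inter = [c for c in net.connections if c.tag in ("interleg", "interseg")]
        # 3 contralateral + 4 ipsilateral pairs, 2 joints each, both
        # directions; full mode doubles the edges by coupling both
        # half-center populations
        assert len(inter) == 7 * per_pair

    def test_hexapod_coupling_is_mutual_and_strong(self):
        net = build_hexapod(HexapodSpec())
        inter = [c for c in net.connections if c.tag in ("interleg", "interseg")]
        present = {(c.source, c.target) for c in inter}
        assert all((t, s) in present for s, t in present)
        assert all(c.synapse.weight == -10.0 for c in inter)

    def test_contralateral_and_neighbour_segments_only(self):
        net = build_hexapod(HexapodSpec())
        inter = {
            (c.source.split(".")[0], c.target.split(".")[0])
            for c in net.connections
            if c.tag in ("interleg", "interseg")
        }
        assert ("FL", "BL") not in inter  # front-back not directly coupled
        assert ("FL", "FR") in inter and ("FL", "ML") in inter

    def test_duplicate_label_rejected(self):
        net = Network()
        net.add_population(PopulationSpec("x", 1, cpg_parameters(-56.0)))
        with pytest.raises(TopologyError):
            net.add_population(PopulationSpec("x", 1, cpg_parameters(-56.0)))

    def test_dangling_edge_rejected(self):
        net = Network()
        net.add_population(PopulationSpec("x", 1, cpg_parameters(-56.0)))
        with pytest.raises(TopologyError):
            net.connect("x", "ghost", SynapseSpec(weight=-1.0))


class TestSimulation:
    def test_empty_network_yields_empty_raster(self):
        raster = run_network(Network(), 100.0, seed=0)
        assert raster.times.size == 0 and raster.ids.size == 0

    def test_single_neuron_deterministic_across_runs(self):
        net = single_neuron_network(noise_std=200.0)
        r1 = run_network(net, 500.0, seed=42)
        r2 = run_network(net, 500.0, seed=42)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.ids, r2.ids)

    def test_different_seeds_differ(self):
        net = single_neuron_network(noise_std=200.0)
        r1 = run_network(net, 500.0, seed=1)
        r2 = run_network(net, 500.0, seed=2)
        assert not np.array_equal(r1.times, r2.times)

    def test_single_neuron_matches_fine_step_reference(self):
        # integration accuracy: spike count over 1 s within +-1 of an
        # independent 100x finer-step integration
        net = single_neuron_network()
        count = run_network(net, 1000.0, seed=0).times.size
        assert abs(count - reference_spike_count(1000.0, 0.001)) <= 1

    def test_halving_dt_changes_count_by_at_most_one(self):
        net = single_neuron_network()
        c1 = run_network(net, 1000.0, dt=0.1, seed=0).times.size
        c2 = run_network(net, 1000.0, dt=0.05, seed=0).times.size
        assert abs(c1 - c2) <= 1

    def test_single_neuron_bursts_with_bimodal_isi(self):
        net = single_neuron_network()
        raster = run_network(net, 3000.0, seed=0)
        isi = np.diff(np.sort(raster.times))
        intra = isi[isi < 50.0]
        inter = isi[isi >= 50.0]
        assert intra.size > 0 and inter.size > 0
        # clear scale separation between within- and between-burst intervals
        assert intra.max() * 5 < inter.min()

    def test_raster_respects_refractory_invariant(self):
        net = build_scpg(cpg_parameters(-56.0), size=2, noise=NoiseSpec(std=800.0))
        raster = run_network(net, 3000.0, seed=3)
        for nid in range(raster.n_neurons):
            isi = np.diff(raster.neuron_spikes(nid))
            assert np.all(isi >= cpg_parameters(-56.0).t_ref - 1e-9)

    def test_both_half_center_populations_stay_active(self, scpg_raster):
        raster = scpg_raster(-56.0, seed=1)
        for label in ("scpg.1", "scpg.2"):
            spikes = raster.population_spikes(label)
            for start in np.arange(1000.0, raster.duration - 2000.0, 2000.0):
                assert np.any((spikes >= start) & (spikes < start + 2000.0))

    def test_conductance_superposition_against_kernel_sum(self):
        # total synaptic conductance at the target equals the brute-force
        # sum of per-spike alpha kernels over all delivered spikes
        net = Network()
        net.add_population(PopulationSpec("src", 1, cpg_parameters(-56.0)))
        net.add_population(
            PopulationSpec("dst", 1, cpg_parameters(-56.0).with_(I_e=0.0), role="motor")
        )
        syn = SynapseSpec(weight=4.0, delay=1.0)
        net.connect("src", "dst", syn)
        sim = Simulator(net, seed=0, record_state=True)
        sim.run(400.0)
        raster = sim.raster()
        src_spikes = raster.population_spikes("src")
        g = np.array([snap[0, 1] for snap in sim.g_trace])  # receptor 0, dst
        times = (np.arange(g.size) + 1) * sim.dt
        expected = np.zeros_like(g)
        for s in src_spikes:
            age = times - (s + syn.delay)
            mask = age >= 0
            expected[mask] += alpha_conductance(age[mask], syn.weight, syn.alpha)
        assert np.allclose(g, expected, rtol=1e-9, atol=1e-12)


class TestSegments:
    def test_degenerate_schedule_equals_plain_run(self):
        net = build_scpg(cpg_parameters(-56.0), size=2, noise=NoiseSpec(std=800.0))
        r1 = run_network(net, 2000.0, seed=9)
        r2 = run_segments(net, [ScheduleSegment(duration=2000.0)], seed=9)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.ids, r2.ids)

    def test_state_carries_across_segment_boundary(self):
        net = build_scpg(cpg_parameters(-56.0), size=2, noise=NoiseSpec(std=800.0))
        one = run_network(net, 2000.0, seed=9)
        two = run_segments(
            net,
            [ScheduleSegment(duration=1000.0), ScheduleSegment(duration=1000.0)],
            seed=9,
        )
        assert np.array_equal(one.times, two.times)
        assert np.array_equal(one.ids, two.ids)

    def test_empty_schedule_rejected(self):
        net = build_scpg(cpg_parameters(-56.0), size=1)
        with pytest.raises(ValueError):
            run_segments(net, [], seed=0)

    def test_threshold_update_shifts_burst_frequency(self):
        net = build_scpg(cpg_parameters(-56.0), size=5, noise=NoiseSpec(std=800.0))
        sched = [
            ScheduleSegment(duration=6000.0, V_T=-56.0),
            ScheduleSegment(duration=6000.0, V_T=-51.0),
        ]
        raster = run_segments(net, sched, seed=1)
        # compare burst rates in the two halves directly from spike times
        spikes = raster.population_spikes("scpg.1")
        first = detect_bursts(spikes[(spikes > 2000) & (spikes < 6000)])
        second = detect_bursts(spikes[(spikes > 8000) & (spikes < 12000)])
        rate_first = len(first) / 4.0
        rate_second = len(second) / 4.0
        assert rate_second > rate_first * 1.5


class TestRasterIO:
    def test_round_trip_through_text_files(self, tmp_path):
        net = build_scpg(cpg_parameters(-56.0), size=1, noise=NoiseSpec(std=300.0))
        raster = run_network(net, 500.0, seed=5)
        p_raster, p_pops = raster.save(tmp_path)
        loaded = SpikeRaster.load(p_raster, p_pops)
        assert np.allclose(loaded.times, raster.times, atol=1e-4)
        assert np.array_equal(loaded.ids, raster.ids)
        assert loaded.populations == raster.populations
        assert loaded.duration == raster.duration

    def test_population_lookup_errors(self):
        raster = SpikeRaster(
            np.array([1.0]), np.array([0]), 10.0, 0.1, {"a": (0, 1)}
        )
        with pytest.raises(KeyError):
            raster.population_spikes("nope")
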