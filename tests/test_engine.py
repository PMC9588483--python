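import numpy as np
import pytest

from barrelsim import engine
from barrelsim.engine import (
    EmptyMapError,
    SpikeRecord,
    UndefinedLatencyError,
    compute_psth,
    peak_latency,
    run_simulation,
)
from barrelsim.thalamus import PSTHInput
from conftest import make_two_neuron_network


def make_record(ids, ts, n_thal=0, n_total=10, duration=100.0):
    return SpikeRecord(neuron_id=np.asarray(ids), t_ms=np.asarray(ts, dtype=float),
                       n_thalamic=n_thal, n_total=n_total, duration_ms=duration, dt=0.1)


class TestRunSimulation:
    def test_no_input_means_no_spikes(self, small_network):
        rec = run_simulation(small_network, None, duration_ms=50.0, seed=0)
        assert rec.n_spikes == 0

    def test_identical_seeds_identical_records(self, small_network):
        trains = engine.principal_thalamic_trial(small_network, rng=3)
        a = run_simulation(small_network, trains, duration_ms=40.0, seed=9)
        b = run_simulation(small_network, trains, duration_ms=40.0, seed=9)
        assert np.array_equal(a.neuron_id, b.neuron_id)
        assert np.array_equal(a.t_ms, b.t_ms)

    def test_network_responds_to_stimulus(self, small_network):
        trains = engine.principal_thalamic_trial(small_network, rng=3)
        rec = run_simulation(small_network, trains, duration_ms=60.0, seed=9, v_r=-60.0)
        ids, _ = rec.cortical()
        assert ids.size > 0

    def test_causality_respects_conduction_delay(self):
        # single thalamic source, one synapse with a 3 ms delay: the
        # postsynaptic cell may not move before the event arrives
        net = make_two_neuron_network(weight=5.0, delay_steps=30)
        trains = [np.array([10.0])]
        rec = run_simulation(net, trains, duration_ms=40.0, seed=0,
                             config=engine.SimulationConfig(
                                 duration_ms=40.0, init_v_sd=0.0),
                             record_v=True, trace_stride=1)
        v = rec.v_traces[:, 0]
        # flat at rest until 10 ms (spike) + 3 ms (delay)
        pre_arrival = v[: int(12.9 / 0.1)]
        assert np.allclose(pre_arrival, pre_arrival[0], atol=1e-9)
        post = v[int(13.5 / 0.1):]
        assert np.max(post) > pre_arrival[0] + 0.1

    def test_failed_synapse_delivers_nothing(self):
        net = make_two_neuron_network(weight=5.0, failure=1.0)
        rec = run_simulation(net, [np.array([5.0])], duration_ms=30.0, seed=0,
                             config=engine.SimulationConfig(duration_ms=30.0,
                                                            init_v_sd=0.0),
                             record_v=True, trace_stride=1)
        v = rec.v_traces[:, 0]
        assert np.allclose(v, v[0], atol=1e-9)


class TestComputePsth:
    def test_empty_record_gives_zero_psth(self):
        rec = make_record([], [])
        psth = compute_psth(rec, np.arange(5), bin_ms=1.0, duration_ms=20.0)
        assert np.all(psth.rates == 0)

    def test_mass_conservation(self):
        rec = make_record([0, 1, 2, 0], [1.0, 2.5, 7.2, 9.9], duration=10.0)
        psth = compute_psth(rec, np.arange(3), bin_ms=1.0)
        total = psth.rates.sum() * 3 * 1e-3  # rate * n * binwidth
        assert total == pytest.approx(4.0)

    def test_uniform_spikes_flat_within_poisson_ci(self):
        rng = np.random.default_rng(0)
        n, rate, dur = 50, 40.0, 1000.0
        ids = np.repeat(np.arange(n), int(rate))
        ts = rng.uniform(0, dur, ids.size)
        psth = compute_psth(make_record(ids, ts, n_total=n, duration=dur),
                            np.arange(n), bin_ms=50.0)
        per_bin = rate * n * 50 / 1000.0
        assert np.all(np.abs(psth.rates / (rate) - 1.0) < 4 * np.sqrt(per_bin) / per_bin)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            compute_psth(make_record([0], [1.0]), np.array([]))


class TestPeakLatency:
    def test_delta_psth(self):
        psth = PSTHInput(np.arange(0.0, 11.0), np.eye(10)[4] * 100)
        assert peak_latency(psth) == pytest.approx(4.5)

    def test_tie_takes_earlier_bin(self):
        rates = np.zeros(10)
        rates[[3, 7]] = 5.0
        assert peak_latency(PSTHInput(np.arange(0.0, 11.0), rates)) == pytest.approx(3.5)

    def test_shift_equivariance(self):
        rates = np.random.default_rng(1).random(20)
        base = peak_latency(PSTHInput(np.arange(0.0, 21.0), rates))
        shifted = peak_latency(PSTHInput(np.arange(0.0, 21.0), np.roll(rates, 4)))
        assert shifted == pytest.approx(base + 4.0)

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedLatencyError):
            peak_latency(PSTHInput(np.arange(0.0, 6.0), np.zeros(5)))


class TestFiringRateByState:
    def test_zero_spikes_gives_zero_table(self, small_network):
        rec = make_record([], [], n_thal=small_network.n_thalamic,
                          n_total=small_network.n_total)
        table = engine.firing_rate_by_state({-70.0: [rec]}, small_network)
        assert (table["mean"] == 0).all()

    def test_hand_built_counts_exact(self, small_network):
        n_thal = small_network.n_thalamic
        pop = small_network.population
        l4e = np.nonzero(pop.select(layer="L4", sign=1))[0][:2] + n_thal
        rec = make_record([l4e[0], l4e[0], l4e[1]], [10.0, 20.0, 30.0],
                          n_thal=n_thal, n_total=small_network.n_total)
        table = engine.firing_rate_by_state({-70.0: [rec, rec]}, small_network)
        row = table[table["class"] == "L4 excitatory"].iloc[0]
        n_l4e = pop.select(layer="L4", sign=1).sum()
        assert row["mean"] == pytest.approx(3.0 / n_l4e)
        assert row["max"] == pytest.approx(2.0)


class TestPresynapticMap:
    def test_single_active_presynaptic_pixel(self, small_network):
        net = small_network
        conn = net.connections
        pop = net.population
        # choose one plastic-pathway edge: cortical pre and post
        ctx = (conn.pre >= net.n_thalamic) & (conn.post >= net.n_thalamic)
        e = np.nonzero(ctx)[0][0]
        pre, post = int(conn.pre[e]), int(conn.post[e])
        rec = make_record([pre, post], [5.0, 20.0], n_thal=net.n_thalamic,
                          n_total=net.n_total)
        post_mask = np.zeros(pop.n_neurons, dtype=bool)
        post_mask[post - net.n_thalamic] = True
        m = engine.spike_triggered_presynaptic_map(rec, net, post_mask)
        assert m.n_triggers == 1
        assert (m.ratio > 0).sum() == 1
        assert m.ratio.max() == pytest.approx(m.n_pixels)
        assert m.ratio.mean() == pytest.approx(1.0)

    def test_ratio_mean_is_one_for_distributed_activity(self, small_network):
        net = small_network
        trains = engine.principal_thalamic_trial(net, rng=3)
        rec = run_simulation(net, trains, duration_ms=60.0, seed=9, v_r=-60.0)
        post_mask = net.population.select(layer="L2/3", sign=1)
        try:
            m = engine.spike_triggered_presynaptic_map(rec, net, post_mask)
        except EmptyMapError:
            pytest.skip("no L2/3 spikes in this realization")
        assert m.ratio.mean() == pytest.approx(1.0, rel=1e-9)

    def test_no_triggers_is_an_error(self, small_network):
        rec = make_record([], [], n_thal=small_network.n_thalamic,
                          n_total=small_network.n_total)
        with pytest.raises(EmptyMapError):
            engine.spike_triggered_presynaptic_map(
                rec, small_network,
                small_network.population.select(layer="L2/3"))


class TestSpikeRecord:
    def test_times_sorted_and_within_duration(self, small_network):
        trains = engine.principal_thalamic_trial(small_network, rng=3)
        rec = run_simulation(small_network, trains, duration_ms=50.0, seed=1)
        assert np.all(np.diff(rec.t_ms) >= 0)
        assert rec.t_ms.size == 0 or (rec.t_ms.min() >= 0 and rec.t_ms.max() < 50.0)

    def test_spikes_by_neuron_partition(self):
        rec = make_record([3, 1, 3], [5.0, 2.0, 9.0])
        sp = rec.spikes_by_neuron()
        assert np.allclose(sp[3], [5.0, 9.0])
        assert np.allclose(sp[1], [2.0])

    def test_hdf5_round_trip(self, tmp_path, small_network):
        import h5py

        rec = make_record([3, 1], [5.0, 2.0], n_thal=0, n_total=5)
        path = tmp_path / "run.h5"
        rec.to_hdf5(path)
        small_network.connections.to_hdf5(path)
        with h5py.File(path) as f:
            assert np.allclose(f["spikes/t_ms"][:], [2.0, 5.0])
            assert f["spikes"].attrs["n_total"] == 5
            assert f["connections/pre"].shape[0] == small_network.connections.n_edges
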