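import numpy as np
import pytest

from barrelsim.thalamus import (
    FilterAndFireNeuron,
    PSTHInput,
    WhiskerTrace,
    apply_surround_transform,
    default_deflection_psth,
    filter_and_fire,
    generate_synthetic_whisking,
    poisson_from_psth,
    random_filter_neurons,
)


def flat_psth(rate_hz=10.0, duration_ms=1000.0, bin_ms=10.0):
    edges = np.arange(0.0, duration_ms + bin_ms, bin_ms)
    return PSTHInput(edges, np.full(edges.size - 1, rate_hz))


class TestPoissonFromPSTH:
    def test_zero_psth_gives_no_spikes(self):
        psth = PSTHInput(np.array([0.0, 50.0, 100.0]), np.zeros(2))
        trains = poisson_from_psth(psth, n_neurons=20, n_trials=3, seed=0)
        assert all(t.size == 0 for trial in trains for t in trial)

    def test_flat_rate_mean_count_ci(self):
        trains = poisson_from_psth(flat_psth(10.0), 200, n_trials=50, seed=1)
        counts = [t.size for trial in trains for t in trial]
        assert 9.0 <= np.mean(counts) <= 11.0

    def test_repeat_mode_reuses_one_realization(self):
        trains = poisson_from_psth(flat_psth(20.0), 10, n_trials=5, seed=2,
                                   repeat_realization=True)
        for trial in trains[1:]:
            for a, b in zip(trains[0], trial):
                assert np.array_equal(a, b)

    def test_across_trial_fano_near_one(self):
        # per-bin counts across 200 independent trials: Fano in [0.8, 1.2]
        psth = default_deflection_psth()
        trains = poisson_from_psth(psth, n_neurons=1, n_trials=200, seed=3)
        edges = psth.bin_edges[::5]
        counts = np.stack([np.histogram(trial[0], bins=edges)[0] for trial in trains])
        m = counts.mean(axis=0)
        keep = m > 0.05
        fano = counts.var(axis=0)[keep] / m[keep]
        assert 0.8 <= fano.mean() <= 1.2

    def test_repeat_mode_fano_is_zero(self):
        psth = default_deflection_psth()
        trains = poisson_from_psth(psth, 1, n_trials=50, seed=4, repeat_realization=True)
        counts = np.stack([np.histogram(t[0], bins=psth.bin_edges)[0] for t in trains])
        assert counts.var(axis=0).max() == 0.0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            PSTHInput(np.array([0.0, 1.0]), np.array([-5.0]))


class TestFilterAndFire:
    def make_trace(self, duration=4000.0, seed=0):
        return generate_synthetic_whisking(duration_ms=duration, seed=seed)

    def test_constant_input_linear_activation_is_homogeneous_poisson(self):
        t = np.arange(0.0, 5000.0, 1.0)
        trace = WhiskerTrace(t, np.zeros(t.size), np.zeros(t.size))
        neuron = FilterAndFireNeuron(kernel=np.array([1.0]), mix=0.0, gain=0.0,
                                     offset=40.0, activation="linear",
                                     refractory_ms=0.0)
        times = filter_and_fire(trace, neuron, seed=5, normalize=False)
        expected = 40.0 * 5.0  # 40 Hz for 5 s
        assert abs(times.size - expected) <= 3 * np.sqrt(expected)

    def test_pure_curvature_neuron_ignores_angle(self):
        trace = self.make_trace(seed=6)
        perturbed = WhiskerTrace(trace.time_ms, trace.angle_deg + 30.0,
                                 trace.curvature_per_mm)
        neuron = random_filter_neurons(1, seed=7)[0]
        neuron = FilterAndFireNeuron(kernel=neuron.kernel, mix=1.0,
                                     gain=neuron.gain, offset=neuron.offset)
        a = filter_and_fire(trace, neuron, seed=8)
        b = filter_and_fire(perturbed, neuron, seed=8)
        assert np.array_equal(a, b)

    def test_refractory_enforced(self):
        trace = self.make_trace(seed=9)
        neuron = FilterAndFireNeuron(kernel=np.array([1.0]), mix=0.0, gain=0.0,
                                     offset=500.0, activation="linear",
                                     max_rate=500.0, refractory_ms=3.0)
        times = filter_and_fire(trace, neuron, seed=10, normalize=False)
        assert times.size > 10
        assert np.min(np.diff(times)) >= 3.0

    def test_low_sampling_rejected(self):
        t = np.arange(0.0, 1000.0, 5.0)  # 200 Hz
        trace = WhiskerTrace(t, np.zeros(t.size), np.zeros(t.size))
        with pytest.raises(ValueError):
            filter_and_fire(trace, random_filter_neurons(1, seed=0)[0])


class TestSurroundTransform:
    def test_psth_impulse_scaled_and_delayed(self):
        psth = PSTHInput(np.array([10.0, 11.0]), np.array([100.0]))
        out = apply_surround_transform(psth)
        assert out.rates[0] == pytest.approx(30.0)
        assert out.bin_edges[0] == pytest.approx(12.5)

    def test_composition(self):
        psth = PSTHInput(np.array([0.0, 1.0]), np.array([1.0]))
        out = apply_surround_transform(apply_surround_transform(psth))
        assert out.rates[0] == pytest.approx(0.09)
        assert out.bin_edges[0] == pytest.approx(5.0)

    def test_zero_maps_to_zero(self):
        psth = PSTHInput(np.array([0.0, 1.0]), np.array([0.0]))
        assert apply_surround_transform(psth).rates[0] == 0.0

    def test_linear_on_arrays(self):
        a, b = np.array([1.0, 2.0]), np.array([0.5, 0.25])
        both = apply_surround_transform(a + b)
        assert np.allclose(both, apply_surround_transform(a) + apply_surround_transform(b))


class TestSyntheticWhisking:
    def test_no_touches_flat_curvature(self):
        trace = generate_synthetic_whisking(2000.0, noise=0.5, seed=11)
        sigma_c = 0.002 * 0.5
        assert np.max(np.abs(trace.curvature_per_mm)) < 5 * sigma_c

    def test_touch_transient_present(self):
        trace = generate_synthetic_whisking(2000.0, touch_times_ms=(800.0,),
                                            touch_curvature_amp=0.05, seed=12)
        after = trace.curvature_per_mm[(trace.time_ms > 800) & (trace.time_ms < 830)]
        assert after.max() > 0.04

    def test_spectral_peak_at_whisk_frequency(self):
        trace = generate_synthetic_whisking(8000.0, whisk_freq_hz=8.0, seed=13)
        sig = trace.angle_deg - trace.angle_deg.mean()
        freqs = np.fft.rfftfreq(sig.size, d=trace.dt_ms / 1000.0)
        power = np.abs(np.fft.rfft(sig)) ** 2
        band = (freqs > 1.0)
        assert abs(freqs[band][np.argmax(power[band])] - 8.0) <= 0.5

    def test_deterministic_under_seed(self):
        a = generate_synthetic_whisking(1000.0, seed=14)
        b = generate_synthetic_whisking(1000.0, seed=14)
        assert np.array_equal(a.angle_deg, b.angle_deg)
        assert np.array_equal(a.curvature_per_mm, b.curvature_per_mm)

    def test_touch_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_whisking(1000.0, touch_times_ms=(1500.0,))

    def test_sampling_is_1_khz(self):
        trace = generate_synthetic_whisking(500.0, seed=15)
        assert trace.sampling_hz == pytest.approx(1000.0)
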