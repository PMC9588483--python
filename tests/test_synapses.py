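import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from barrelsim.synapses import (
    KernelFitError,
    PSCKernel,
    STPState,
    apply_failures,
    fit_double_exponential,
    kernel_shape_stats,
    stp_amplitude_factor,
    stp_update,
    synaptic_current,
)


class TestKernel:
    @given(tau_rise=st.floats(0.1, 5.0), ratio=st.floats(1.5, 30.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_normalized_peak_is_one(self, tau_rise, ratio):
        k = PSCKernel(tau_rise, tau_rise * ratio)
        assert k(np.array([k.t_peak]))[0] == pytest.approx(1.0, abs=1e-6)
        t = np.linspace(0, k.t_peak + 10 * k.tau_decay, 5000)
        assert np.max(k(t)) <= 1.0 + 1e-9

    def test_kernel_zero_before_onset(self):
        k = PSCKernel(0.5, 5.0)
        assert np.all(k(np.linspace(-10, -0.01, 50)) == 0.0)

    def test_alpha_function_limit(self):
        k = PSCKernel(2.0, 2.0)
        t = np.array([2.0])  # alpha function peaks at tau
        assert k(t)[0] == pytest.approx(1.0)
        assert k(np.array([4.0]))[0] == pytest.approx((4 / 2) * np.exp(1 - 2))

    def test_fit_round_trip_within_one_percent(self):
        k0 = PSCKernel(0.5, 5.0)
        rise, hw = kernel_shape_stats(k0)
        k1, amp = fit_double_exponential(1.3, rise, hw)
        assert amp == 1.3
        assert k1.tau_rise == pytest.approx(0.5, rel=0.01)
        assert k1.tau_decay == pytest.approx(5.0, rel=0.01)

    @pytest.mark.parametrize("rise,hw", [(2.0, 1.0), (3.0, 3.0)])
    def test_infeasible_shape_targets_rejected(self, rise, hw):
        with pytest.raises(KernelFitError):
            fit_double_exponential(1.0, rise, hw)


class TestShortTermPlasticity:
    def test_spike_jump_is_multiplicative(self):
        s = stp_update(STPState(x=1.0, p=0.5, tau_x=150.0), dt=0.0, spike=True)
        assert s.x == pytest.approx(0.5)

    def test_closed_form_recovery_after_tau(self):
        s = STPState(x=1.0, p=0.5, tau_x=150.0)
        s = stp_update(s, dt=0.0, spike=True)          # x -> 0.5
        s = stp_update(s, dt=150.0, spike=False)       # recover one tau
        assert s.x == pytest.approx(1 - 0.5 * np.exp(-1), rel=1e-12)

    def test_facilitation_overshoots_then_relaxes(self):
        s = STPState(x=1.0, p=1.3, tau_x=100.0)
        s = stp_update(s, dt=0.0, spike=True)
        assert s.x == pytest.approx(1.3)
        s = stp_update(s, dt=1000.0, spike=False)
        assert s.x == pytest.approx(1.0, abs=1e-4)

    def test_memoryless_beyond_five_tau(self):
        for x0 in (0.1, 1.9):
            s = stp_update(STPState(x=x0, p=0.5, tau_x=150.0), dt=5 * 150.0, spike=False)
            assert abs(s.x - 1.0) < np.exp(-5)

    def test_paired_pulse_amplitude_closed_form(self):
        # second-pulse factor: p * (1 - (1-p) exp(-dt/tau))
        p, tau, gap = 0.7, 150.0, 50.0
        s = STPState(x=1.0, p=p, tau_x=tau)
        s = stp_update(s, dt=0.0, spike=True)
        s = stp_update(s, dt=gap, spike=True)
        assert s.x == pytest.approx(stp_amplitude_factor(p, tau, gap), rel=1e-12)


class TestFailures:
    def test_zero_rate_delivers_all(self):
        t = np.arange(100.0)
        assert apply_failures(t, 0.0, seed=0).size == 100

    def test_unit_rate_delivers_none(self):
        assert apply_failures(np.arange(100.0), 1.0, seed=0).size == 0

    def test_half_rate_binomial_ci(self):
        t = np.arange(10000.0)
        kept = apply_failures(t, 0.5, seed=2).size
        assert abs(kept - 5000) <= 3 * np.sqrt(10000 * 0.25)

    def test_thinned_poisson_stays_poisson(self):
        # Bernoulli thinning of a Poisson train is Poisson at the scaled
        # rate: KS test on exponential inter-event intervals, 10 seeds
        rate, frac = 50.0, 0.6
        pvals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            isi = rng.exponential(1 / rate, 4000)
            times = np.cumsum(isi)
            kept = apply_failures(times, 1 - frac, seed=seed + 100)
            gaps = np.diff(kept)
            pvals.append(stats.kstest(gaps, "expon",
                                      args=(0, 1 / (rate * frac))).pvalue)
        assert min(pvals) > 0.01

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_failures(np.arange(3.0), 1.5)


class TestSynapticCurrent:
    def test_single_event_peaks_at_weight(self):
        k = PSCKernel(0.5, 5.0)
        t = np.linspace(0, 40, 4000)
        cur = synaptic_current(t, [5.0], [2.0], k)
        assert np.max(cur) == pytest.approx(2.0, rel=1e-4)
        assert t[np.argmax(cur)] == pytest.approx(5.0 + k.t_peak, abs=0.05)

    def test_linear_superposition(self):
        k = PSCKernel(0.5, 5.0)
        t = np.linspace(0, 200, 2000)
        both = synaptic_current(t, [10.0, 150.0], [1.0, 1.0], k)
        single = synaptic_current(t, [10.0], [1.0], k) + synaptic_current(t, [150.0], [1.0], k)
        assert np.allclose(both, single)

    def test_inhibitory_sign(self):
        k = PSCKernel(0.5, 5.0, sign=-1)
        cur = synaptic_current(np.array([7.0]), [5.0], [1.0], k)
        assert cur < 0

    def test_paired_pulse_peak_ratio(self):
        # second PSP peak carries the STP factor from the closed form
        p, tau, gap = 0.7, 150.0, 50.0
        k = PSCKernel(0.5, 5.0)
        f1, f2 = p, stp_amplitude_factor(p, tau, gap)
        t = np.linspace(0, 100, 10000)
        cur = synaptic_current(t, [0.0, gap], [f1, f2], k)
        peak1 = cur[(t > 0) & (t < gap)].max()
        peak2 = cur[t > gap].max()
        assert peak2 / peak1 == pytest.approx(f2 / f1, abs=0.02)
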