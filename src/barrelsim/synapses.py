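"""Synaptic currents, short-term plasticity and transmission failures.

Postsynaptic currents are double-exponential kernels

    K(t) = N * (exp(-t/tau_decay) - exp(-t/tau_rise)),   t >= 0,

normalized so the kernel peak equals 1; the degenerate tau_rise ->
tau_decay limit is the alpha function (t/tau) exp(1 - t/tau).  Kernel
time constants are fit numerically so that the normalized shape
reproduces a requested 10-90% rise time and half-width, the statistics
by which synaptic physiology is usually reported.

Short-term plasticity follows a single resource variable x that relaxes
to 1 with time constant tau_x (150 ms for excitatory and depressing
inhibitory synapses, 100 ms for facilitating inhibitory ones) and jumps
multiplicatively, x <- p x, each time the presynaptic neuron fires.  The
delivered amplitude of an event uses the post-jump x, so a paired pulse
at interval Dt has amplitude ratio 1 - (1 - p) exp(-Dt/tau_x).

Transmission failures are independent per-spike Bernoulli deletions at a
fixed pathway-specific rate, and amplitude variability (the measured CV)
is per-event multiplicative Gaussian jitter truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "PSCKernel",
    "STPState",
    "KernelFitError",
    "fit_double_exponential",
    "kernel_shape_stats",
    "stp_update",
    "stp_amplitude_factor",
    "apply_failures",
    "synaptic_current",
]


class KernelFitError(RuntimeError):
    """Requested rise/half-width shape is not attainable by the kernel family."""


@dataclass(frozen=True)
class PSCKernel:
    """Normalized double-exponential kernel (peak = 1)."""

    tau_rise: float    # ms
    tau_decay: float   # ms
    sign: int = 1      # +1 excitatory, -1 inhibitory

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise <= self.tau_decay):
            raise ValueError("need 0 < tau_rise <= tau_decay")

    @property
    def is_alpha(self) -> bool:
        return np.isclose(self.tau_rise, self.tau_decay, rtol=1e-9)

    @property
    def t_peak(self) -> float:
        if self.is_alpha:
            return self.tau_decay
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def peak_scale(self) -> float:
        """1 / (unnormalized kernel value at its peak)."""
        if self.is_alpha:
            return 1.0
        tp, tr, td = self.t_peak, self.tau_rise, self.tau_decay
        return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))

    def __call__(self, t) -> np.ndarray:
        """Normalized kernel value; 0 for t < 0."""
        t = np.asarray(t, dtype=float)
        if self.is_alpha:
            val = (t / self.tau_decay) * np.exp(1.0 - t / self.tau_decay)
        else:
            val = self.peak_scale * (np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise))
        return np.where(t >= 0.0, val, 0.0)

    def sampled(self, dt: float, t_max: float | None = None) -> np.ndarray:
        """Kernel sampled on a dt grid out to ~8 decay constants."""
        if t_max is None:
            t_max = self.t_peak + 8.0 * self.tau_decay
        return self(np.arange(0.0, t_max, dt))


def kernel_shape_stats(kernel: PSCKernel) -> tuple[float, float]:
    """(10-90% rise time, half-width) of the normalized kernel, ms."""
    tp = kernel.t_peak
    f = lambda t, level: kernel(t) - level
    t10 = brentq(f, 1e-12, tp, args=(0.1,))
    t90 = brentq(f, 1e-12, tp, args=(0.9,))
    left = brentq(f, 1e-12, tp, args=(0.5,))
    hi = tp
    while kernel(hi) > 0.5:
        hi += 4.0 * kernel.tau_decay
    right = brentq(f, tp, hi, args=(0.5,))
    return (t90 - t10, right - left)


def fit_double_exponential(
    peak_amp: float,
    rise_time_10_90: float,
    half_width: float,
    sign: int = 1,
    rel_tol: float = 0.01,
) -> tuple[PSCKernel, float]:
    """Fit (tau_rise, tau_decay) so the kernel matches rise and half-width.

    Returns ``(kernel, amplitude)`` where amplitude is just ``peak_amp``
    carried through (the normalized kernel peaks at 1).  Raises
    :class:`KernelFitError` when the targets cannot be met within
    ``rel_tol`` relative error (e.g. half_width <= rise time).
    """
    if min(peak_amp, rise_time_10_90, half_width) <= 0:
        raise ValueError("all shape targets must be > 0")
    if half_width <= rise_time_10_90:
        raise KernelFitError("half_width must exceed the 10-90% rise time")

    target = np.array([rise_time_10_90, half_width])

    def residuals(logtaus):
        tr, td = np.exp(logtaus)
        if tr >= td:
            tr = td * (1 - 1e-9)
        k = PSCKernel(tau_rise=tr, tau_decay=td, sign=sign)
        got = np.array(kernel_shape_stats(k))
        return (got - target) / target

    x0 = np.log([max(rise_time_10_90 / 2.2, 1e-3), max(half_width / np.log(2.0) / 1.5, 2e-3)])
    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    tr, td = np.exp(sol.x)
    if tr > td:
        tr, td = td, tr
    kernel = PSCKernel(tau_rise=min(tr, td), tau_decay=max(tr, td), sign=sign)
    err = np.abs(residuals(np.log([kernel.tau_rise, kernel.tau_decay]))).max()
    if err > rel_tol:
        raise KernelFitError(
            f"shape targets infeasible: best fit misses by {err:.1%} "
            f"(rise {rise_time_10_90} ms, half-width {half_width} ms)"
        )
    return kernel, float(peak_amp)


@dataclass
class STPState:
    """Short-term plasticity resource variable for one (or many) synapses."""

    x: np.ndarray | float = 1.0
    p: np.ndarray | float = 1.0
    tau_x: np.ndarray | float = 150.0   # ms

    def copy(self) -> "STPState":
        return replace(self, x=np.array(self.x, dtype=float, copy=True))


def stp_update(state: STPState, dt: float, spike) -> STPState:
    """Advance the resource variable by dt, then apply the spike jump.

    Relaxation is the exact exponential solution of dx/dt = (1 - x)/tau_x
    (the resting resource level is 1); on a spike x <- p x.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    x = np.asarray(state.x, dtype=float)
    decay = np.exp(-dt / np.asarray(state.tau_x, dtype=float))
    x = 1.0 - (1.0 - x) * decay
    spike = np.asarray(spike, dtype=bool)
    x = np.where(spike, np.asarray(state.p, dtype=float) * x, x)
    if x.ndim == 0:
        x = float(x)
    return STPState(x=x, p=state.p, tau_x=state.tau_x)


def stp_amplitude_factor(p: float, tau_x: float, interval_ms: float) -> float:
    """Closed-form post-jump resource at the second of a spike pair.

    First spike from rest: factor p.  After ``interval_ms`` of recovery the
    second spike's factor is p * (1 - (1 - p) exp(-interval/tau_x)).
    """
    return p * (1.0 - (1.0 - p) * np.exp(-interval_ms / tau_x))


def apply_failures(presyn_spike_times, failure_rate: float,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Independently drop each spike with probability ``failure_rate``."""
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must lie in [0, 1]")
    times = np.asarray(presyn_spike_times, dtype=float)
    if failure_rate == 0.0:
        return times.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(times.shape) >= failure_rate
    return times[keep]


def synaptic_current(
    t,
    event_times,
    event_amplitudes,
    kernel: PSCKernel,
) -> np.ndarray:
    """Superpose kernel responses of delivered events at time(s) t (ms).

    ``event_amplitudes`` already include weight, STP factor and jitter;
    the kernel sign sets excitation vs inhibition.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    times = np.asarray(event_times, dtype=float)
    amps = np.asarray(event_amplitudes, dtype=float)
    lags = t[:, None] - times[None, :]
    out = (kernel(lags) * amps[None, :]).sum(axis=1) * kernel.sign
    return out if out.size > 1 else float(out[0])
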