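"""Thalamic (VPM) input generation.

Two encoding modes drive the cortical column:

* **PSTH-constrained Poisson** — every barreloid neuron fires an
  independent inhomogeneous Poisson train whose rate follows a shared
  population PSTH (the anesthetized single-deflection response).  A
  repeat mode reuses one realization across trials, which removes all
  thalamic trial-to-trial variability while preserving rate and timing.

* **Filter-and-fire** — each neuron linearly filters a mixture of the
  whisker angle and curvature channels, passes the result through a
  monotone activation to an instantaneous rate, and spikes as an
  inhomogeneous Poisson process with an absolute refractory period.

Surround (non-principal) whiskers receive the same stimulus scaled to
30% of the original amplitude and delayed by 2.5 ms.

A synthetic whisking generator stands in for recorded freely-whisking
data: two channels at 1 kHz, angle (degrees) with rhythmic whisking and
slow set-point drift, and curvature (1/mm) with brief decaying
transients at configurable touch times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Barreloid",
    "PSTHInput",
    "WhiskerTrace",
    "FilterAndFireNeuron",
    "poisson_from_psth",
    "filter_and_fire",
    "random_filter_neurons",
    "apply_surround_transform",
    "generate_synthetic_whisking",
    "default_deflection_psth",
    "SURROUND_AMPLITUDE",
    "SURROUND_DELAY_MS",
]

#: surround-whisker transform constants
SURROUND_AMPLITUDE = 0.30
SURROUND_DELAY_MS = 2.5


@dataclass(frozen=True)
class PSTHInput:
    """Population firing-rate histogram: edges (ms) and rate per bin (Hz)."""

    bin_edges: np.ndarray     # (n_bins + 1,), ms
    rates: np.ndarray         # (n_bins,), spikes/s per neuron

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if edges.ndim != 1 or rates.shape != (edges.size - 1,):
            raise ValueError("need n_bins+1 edges for n_bins rates")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must increase")
        if np.any(rates < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "rates", rates)

    @property
    def duration(self) -> float:
        return float(self.bin_edges[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.bin_edges[:-1], "rate_hz": self.rates})

    def surround(self) -> "PSTHInput":
        return apply_surround_transform(self)


@dataclass(frozen=True)
class Barreloid:
    """A VPM cell cluster feeding one cortical column."""

    n_neurons: int = 200
    role: str = "principal"   # or "surround"

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.role not in ("principal", "surround"):
            raise ValueError("role must be 'principal' or 'surround'")


@dataclass(frozen=True)
class WhiskerTrace:
    """Whisker angle/curvature time series at uniform sampling."""

    time_ms: np.ndarray
    angle_deg: np.ndarray
    curvature_per_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        if t.size < 2 or not np.allclose(np.diff(t), t[1] - t[0]):
            raise ValueError("time base must be uniform")
        for arr in (self.angle_deg, self.curvature_per_mm):
            if np.asarray(arr).shape != t.shape or not np.isfinite(arr).all():
                raise ValueError("channels must match the time base and be finite")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.time_ms, "angle_deg": self.angle_deg,
             "curvature_per_mm": self.curvature_per_mm}
        )


def default_deflection_psth(
    duration_ms: float = 100.0,
    bin_ms: float = 1.0,
    onset_ms: float = 5.0,
    tau_ms: float = 2.0,
    spikes_per_stimulus: float = 1.5,
    baseline_hz: float = 0.5,
) -> PSTHInput:
    """Stand-in anesthetized single-deflection VPM PSTH.

    A gamma-shaped onset (sharp rise ~2 ms after stimulus arrival at
    ``onset_ms``, exponential decay, peak near ``onset_ms + tau_ms``)
    scaled to integrate to ``spikes_per_stimulus`` per neuron, on a small
    spontaneous baseline.  The published PSTH values are not reproduced
    here; this shape is an editable synthetic surrogate.
    """
    edges = np.arange(0.0, duration_ms + bin_ms, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    s = np.maximum(centers - onset_ms, 0.0)
    shape = (s / tau_ms**2) * np.exp(-s / tau_ms)       # integrates to ~1 (1/ms)
    rates = baseline_hz + spikes_per_stimulus * shape * 1000.0
    return PSTHInput(bin_edges=edges, rates=rates)


def poisson_from_psth(
    psth: PSTHInput,
    n_neurons: int,
    n_trials: int = 1,
    seed: int | np.random.Generator = 0,
    repeat_realization: bool = False,
) -> list[list[np.ndarray]]:
    """Independent inhomogeneous Poisson trains constrained by the PSTH.

    Returns ``trains[trial][neuron]`` = sorted spike-time array (ms).  With
    ``repeat_realization`` one draw is reused for every trial (no thalamic
    trial-to-trial variability).
    """
    rng = np.random.default_rng(seed)
    widths = np.diff(psth.bin_edges) * 1e-3           # s
    lam = psth.rates * widths                         # expected count per bin

    def one_trial() -> list[np.ndarray]:
        counts = rng.poisson(lam[None, :].repeat(n_neurons, axis=0))
        out = []
        for row in counts:
            ts = []
            nz = np.nonzero(row)[0]
            for b in nz:
                ts.append(rng.uniform(psth.bin_edges[b], psth.bin_edges[b + 1], row[b]))
            out.append(np.sort(np.concatenate(ts)) if ts else np.empty(0))
        return out

    if repeat_realization:
        once = one_trial()
        return [[t.copy() for t in once] for _ in range(n_trials)]
    return [one_trial() for _ in range(n_trials)]


@dataclass(frozen=True)
class FilterAndFireNeuron:
    """Linear filter -> monotone activation -> Poisson spiking encoder.

    ``mix`` in [0, 1] weights curvature against angle (1 = pure
    curvature).  The activation is a saturating sigmoid in the filtered,
    z-scored input: rate = max_rate / (1 + exp(-gain (y - offset))), or a
    rectified-linear ramp when ``activation='linear'``.
    """

    kernel: np.ndarray                 # filter taps at the trace sampling dt
    mix: float = 0.5
    gain: float = 2.0
    offset: float = 1.0
    max_rate: float = 200.0            # spikes/s
    refractory_ms: float = 1.0
    activation: str = "sigmoid"
    delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix <= 1.0:
            raise ValueError("mix must lie in [0, 1]")
        if self.max_rate < 0 or self.refractory_ms < 0:
            raise ValueError("rates and refractory must be >= 0")
        if self.activation not in ("sigmoid", "linear"):
            raise ValueError("activation must be 'sigmoid' or 'linear'")

    def rate(self, trace: WhiskerTrace, normalize: bool = True) -> np.ndarray:
        """Instantaneous firing rate (Hz) along the trace."""
        ang = np.asarray(trace.angle_deg, dtype=float)
        cur = np.asarray(trace.curvature_per_mm, dtype=float)
        if normalize:
            ang = (ang - ang.mean()) / (ang.std() + 1e-12)
            cur = (cur - cur.mean()) / (cur.std() + 1e-12)
        x = self.mix * cur + (1.0 - self.mix) * ang
        y = np.convolve(x, self.kernel)[: x.size]
        if self.activation == "sigmoid":
            r = self.max_rate / (1.0 + np.exp(-self.gain * (y - self.offset)))
        else:
            r = np.clip(self.gain * y + self.offset, 0.0, None)
        if self.delay_ms > 0:
            shift = int(round(self.delay_ms / trace.dt_ms))
            r = np.concatenate([np.zeros(shift), r])[: r.size]
        return r


def _biphasic_kernel(dt_ms: float, tau1: float, tau2: float, ratio: float,
                     latency_ms: float, length_ms: float = 50.0) -> np.ndarray:
    t = np.arange(0.0, length_ms, dt_ms)
    k = (t / tau1) * np.exp(1 - t / tau1) - ratio * (t / tau2) * np.exp(1 - t / tau2)
    shift = int(round(latency_ms / dt_ms))
    k = np.concatenate([np.zeros(shift), k])[: t.size]
    norm = np.abs(k).sum() * dt_ms
    return k / (norm + 1e-12)


def random_filter_neurons(
    n: int,
    dt_ms: float = 1.0,
    seed: int | np.random.Generator = 0,
    max_rate: float = 200.0,
) -> list[FilterAndFireNeuron]:
    """Randomized bank of filter-and-fire encoders.

    Biphasic difference-of-alpha filters with randomized widths, latency
    and polarity; sigmoidal activations with randomized gain/offset; mix
    weights spanning angle-only to curvature-only cells.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        tau1 = rng.uniform(2.0, 8.0)
        tau2 = tau1 * rng.uniform(1.5, 3.0)
        kernel = _biphasic_kernel(
            dt_ms,
            tau1,
            tau2,
            ratio=rng.uniform(0.3, 0.9),
            latency_ms=rng.uniform(1.0, 6.0),
        ) * rng.choice([-1.0, 1.0])
        out.append(
            FilterAndFireNeuron(
                kernel=kernel,
                mix=rng.choice([0.0, 1.0, rng.uniform(0.2, 0.8)]),
                gain=rng.uniform(1.0, 4.0),
                offset=rng.uniform(0.5, 2.0),
                max_rate=max_rate,
                refractory_ms=1.0,
            )
        )
    return out


def filter_and_fire(
    trace: WhiskerTrace,
    neuron: FilterAndFireNeuron,
    seed: int | np.random.Generator = 0,
    normalize: bool = True,
) -> np.ndarray:
    """Spike times (ms) of one encoder driven by a whisker trace.

    Inhomogeneous Poisson sampling by thinning at the trace resolution,
    with an absolute refractory period.
    """
    if trace.sampling_hz < 500.0:
        raise ValueError("trace sampling must be at least 500 Hz")
    rng = np.random.default_rng(seed)
    rate = neuron.rate(trace, normalize=normalize)
    dt_s = trace.dt_ms * 1e-3
    p = np.clip(rate * dt_s, 0.0, 1.0)
    hits = rng.random(p.size) < p
    times = trace.time_ms[hits]
    if neuron.refractory_ms > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= neuron.refractory_ms:
                kept.append(t)
        times = np.asarray(kept)
    return times


def apply_surround_transform(stimulus, amplitude: float = SURROUND_AMPLITUDE,
                             delay_ms: float = SURROUND_DELAY_MS):
    """Surround-whisker transform: scale to 30%, delay by 2.5 ms.

    Accepts a :class:`PSTHInput` (rates scaled, edges shifted) or a plain
    array interpreted as amplitudes with an attached time axis elsewhere.
    The transform is linear and commutes with superposition.
    """
    if isinstance(stimulus, PSTHInput):
        return PSTHInput(bin_edges=stimulus.bin_edges + delay_ms,
                         rates=stimulus.rates * amplitude)
    arr = np.asarray(stimulus, dtype=float)
    return arr * amplitude


@dataclass(frozen=True)
class SurroundEvent:
    """Helper for the impulse algebra of the surround transform."""

    time_ms: float
    amplitude: float

    def transformed(self) -> "SurroundEvent":
        return SurroundEvent(self.time_ms + SURROUND_DELAY_MS,
                             self.amplitude * SURROUND_AMPLITUDE)


def generate_synthetic_whisking(
    duration_ms: float = 4000.0,
    whisk_freq_hz: float = 8.0,
    whisk_amp_deg: float = 15.0,
    touch_times_ms: tuple[float, ...] = (),
    touch_curvature_amp: float = 0.05,
    noise: float = 0.5,
    seed: int | np.random.Generator = 0,
    sampling_hz: float = 1000.0,
    setpoint_amp_deg: float = 5.0,
    curvature_baseline: float = 0.0,
    touch_decay_ms: float = 25.0,
) -> WhiskerTrace:
    """Synthetic freely-whisking stimulus emulating head-fixed recordings.

    Angle = slow set-point drift + sinusoidal whisking at ``whisk_freq_hz``
    (amplitude in degrees) + white noise.  Curvature = baseline + brief
    touch-evoked transients (2 ms rise, ``touch_decay_ms`` decay, peak
    ``touch_curvature_amp`` 1/mm) + scaled white noise.  1 kHz sampling by
    default.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    for tt in touch_times_ms:
        if not 0.0 <= tt < duration_ms:
            raise ValueError(f"touch time {tt} ms outside the trace")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_hz
    t = np.arange(0.0, duration_ms, dt)
    phase = rng.uniform(0, 2 * np.pi)
    setpoint = setpoint_amp_deg * np.sin(2 * np.pi * 0.4 * t / 1000.0 + rng.uniform(0, 2 * np.pi))
    angle = (
        setpoint
        + whisk_amp_deg * np.sin(2 * np.pi * whisk_freq_hz * t / 1000.0 + phase)
        + noise * rng.standard_normal(t.size)
    )
    curv = curvature_baseline + 0.002 * noise * rng.standard_normal(t.size)
    for tt in touch_times_ms:
        s = t - tt
        transient = np.where(
            s >= 0.0,
            (1.0 - np.exp(-np.maximum(s, 0.0) / 2.0)) * np.exp(-np.maximum(s, 0.0) / touch_decay_ms),
            0.0,
        )
        peak = transient.max() if transient.max() > 0 else 1.0
        curv = curv + touch_curvature_amp * transient / peak
    return WhiskerTrace(time_ms=t, angle_deg=angle, curvature_per_mm=curv)
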