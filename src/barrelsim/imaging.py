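"""Forward model from spike trains to calcium fluorescence at 7 Hz.

Per imaging frame (interval dt_C = 1000/7 ~ 143 ms) the calcium
concentration of each neuron follows the discrete update

    C(t + dt_C) = C(t) + dC
    dC = -(dt_C / tau_C) (C - C_b) + A_C N_spikes_in_frame
         + sigma_C sqrt(dt_C) eta_C,

with tau_C = 500 ms, baseline C_b = 0.1 a.u., A_C = 5 a.u. per spike and
standard-normal eta_C.  The luminescence is a linear readout
L = alpha C + beta + sigma_f eta_f (alpha = 1, beta = 0, sigma_f = 1).

The published update is written as an increment "dL" with the same
right-hand side; accumulating that increment would integrate the calcium
trace a second time, so the default reading assigns L each frame
(``luminescence_mode='assign'``).  The literal accumulation is available
as ``luminescence_mode='accumulate'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalciumParams", "simulate_fluorescence", "frame_difference"]


@dataclass(frozen=True)
class CalciumParams:
    """Constants of the calcium/fluorescence forward model (a.u., ms)."""

    tau_C: float = 500.0
    C_b: float = 0.1
    A_C: float = 5.0
    sigma_C: float = 1.0
    dt_C: float = 1000.0 / 7.0
    alpha_F: float = 1.0
    beta_F: float = 0.0
    sigma_f: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_C <= 0 or self.dt_C <= 0:
            raise ValueError("tau_C and dt_C must be > 0")


def simulate_fluorescence(
    spike_times: np.ndarray | list[np.ndarray],
    duration_ms: float,
    params: CalciumParams = CalciumParams(),
    seed: int | np.random.Generator = 0,
    luminescence_mode: str = "assign",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render spike trains into per-frame calcium and luminescence traces.

    ``spike_times`` is one array of spike times (ms) per neuron (a single
    array is treated as one neuron).  Returns ``(frame_times, C, L)``
    where C and L have shape (n_frames, n_neurons); frame f covers
    ``[f * dt_C, (f+1) * dt_C)`` and reports the state at the end of the
    frame.
    """
    if luminescence_mode not in ("assign", "accumulate"):
        raise ValueError("luminescence_mode must be 'assign' or 'accumulate'")
    if isinstance(spike_times, np.ndarray) and spike_times.ndim == 1:
        trains = [spike_times]
    else:
        trains = list(spike_times)
    rng = np.random.default_rng(seed)
    n = len(trains)
    n_frames = int(np.ceil(duration_ms / params.dt_C))
    edges = np.arange(n_frames + 1) * params.dt_C
    counts = np.zeros((n_frames, n), dtype=float)
    for j, ts in enumerate(trains):
        ts = np.asarray(ts, dtype=float)
        if ts.size and (ts.min() < 0 or ts.max() >= duration_ms):
            raise ValueError("spike times must lie within [0, duration)")
        counts[:, j], _ = np.histogram(ts, bins=edges)

    C = np.empty((n_frames, n))
    L = np.empty((n_frames, n))
    c = np.full(n, params.C_b)
    lum = params.alpha_F * c + params.beta_F
    leak = params.dt_C / params.tau_C
    for f in range(n_frames):
        eta_c = rng.standard_normal(n) if params.sigma_C > 0 else 0.0
        c = c + (-leak * (c - params.C_b) + params.A_C * counts[f]
                 + params.sigma_C * np.sqrt(params.dt_C) * eta_c)
        eta_f = rng.standard_normal(n) if params.sigma_f > 0 else 0.0
        if luminescence_mode == "assign":
            lum = params.alpha_F * c + params.beta_F + params.sigma_f * eta_f
        else:
            lum = lum + params.alpha_F * c + params.beta_F + params.sigma_f * eta_f
        C[f] = c
        L[f] = lum
    frame_times = edges[1:]
    return frame_times, C, L


def frame_difference(
    L_frames: np.ndarray,
    touch_frame_index: int,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron luminescence change across a touch frame.

    Returns ``(delta, hist_counts, hist_edges)`` where delta is
    L(one frame after touch) - L(one frame before touch) per neuron and
    the histogram summarizes the population (its counts sum to the neuron
    count).
    """
    L = np.asarray(L_frames, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    if not 1 <= touch_frame_index < L.shape[0] - 1:
        raise IndexError("touch frame must have a frame before and after it")
    delta = L[touch_frame_index + 1] - L[touch_frame_index - 1]
    counts, edges = np.histogram(delta, bins=n_bins)
    return delta, counts, edges


def fluorescence_frame(L_frames: np.ndarray, frame_index: int) -> np.ndarray:
    """Single-frame luminescence vector (convenience accessor)."""
    return np.asarray(L_frames)[frame_index]


def traces_to_frame(frame_times: np.ndarray, L: np.ndarray) -> pd.DataFrame:
    """Long-format (frame_time_ms, neuron_id, L) table for export."""
    n_frames, n = L.shape
    return pd.DataFrame(
        {
            "frame_time_ms": np.repeat(frame_times, n),
            "neuron_id": np.tile(np.arange(n), n_frames),
            "L": L.ravel(),
        }
    )
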