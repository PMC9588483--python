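"""Izhikevich membrane dynamics with history-dependent spike thresholds.

The membrane model is the quadratic two-variable form

    dv/dt = 0.04 (v - v_r)(v - v_t) - u + I
    du/dt = a (b (v - v_r) - u)

integrated with forward Euler at dt = 0.1 ms.  On a spike, v resets to c
and u jumps by d.  Spike emission uses one of three threshold modes:

* ``fixed``    — the classic 30 mV peak condition (pure quadratic model);
* ``simple``   — theta(t) = -0.99 s - 40.2 mV, where s is the mean dv/dt
                 (mV/ms) over the trailing 5 ms window, so fast-rising
                 depolarization lowers the threshold;
* ``adaptive`` — a first-order threshold ODE
                 tau_theta dtheta/dt = theta_inf(v) - theta with
                 theta_inf(v) = alpha (v - v_i) + v_T
                               + k_alpha log(1 + exp((v - v_i)/k_i)),
                 evaluated with a numerically stable softplus.

In the ``simple``/``adaptive`` modes a spike is emitted when v crosses
theta from below (the suprathreshold upstroke is not modeled in detail);
in every mode v >= 30 mV also triggers a spike so the quadratic blow-up
is always caught.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdaptiveThresholdParams",
    "IzhikevichState",
    "IntegrationBlowupError",
    "euler_step",
    "threshold_simple",
    "threshold_adaptive_step",
    "theta_inf",
    "SLOPE_WINDOW_MS",
    "PEAK_MV",
]

#: trailing window for the EPSP-slope threshold, ms
SLOPE_WINDOW_MS = 5.0
#: hard spike-peak cap, mV
PEAK_MV = 30.0
#: intercept and slope gain of the simple threshold rule, mV
SIMPLE_THETA_INTERCEPT = -40.2
SIMPLE_THETA_GAIN = -0.99


class IntegrationBlowupError(FloatingPointError):
    """State became non-finite during integration."""


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    """Constants of the adaptive (first-order ODE) spike threshold."""

    tau_theta: float = 5.0    # ms
    alpha: float = 0.2        # dimensionless
    v_i: float = -60.0        # mV
    v_T: float = -45.0        # mV
    k_alpha: float = 5.0      # mV
    k_i: float = 2.0          # mV

    def __post_init__(self) -> None:
        if self.tau_theta <= 0:
            raise ValueError("tau_theta must be > 0")
        if self.k_i <= 0:
            raise ValueError("k_i must be > 0")


@dataclass
class IzhikevichState:
    """Vectorized membrane state; all arrays share one shape."""

    v: np.ndarray
    u: np.ndarray
    theta: np.ndarray
    # circular buffer of recent dv values (window_steps, n); used by the
    # 'simple' threshold to form the trailing 5 ms mean slope
    slope_buffer: np.ndarray | None = None
    buffer_pos: int = 0

    @classmethod
    def initial(cls, n: int, v0: float | np.ndarray = -70.0, b: float | np.ndarray = 0.2,
                v_r: float | np.ndarray = -70.0, theta0: float = SIMPLE_THETA_INTERCEPT,
                dt: float = 0.1) -> "IzhikevichState":
        v = np.broadcast_to(np.asarray(v0, float), (n,)).copy()
        u = np.asarray(b, float) * (v - np.asarray(v_r, float))
        window = int(round(SLOPE_WINDOW_MS / dt))
        return cls(
            v=v,
            u=np.broadcast_to(u, (n,)).copy(),
            theta=np.full(n, float(theta0)),
            slope_buffer=np.zeros((window, n)),
            buffer_pos=0,
        )


def threshold_simple(slope_buffer: np.ndarray, dt: float = 0.1) -> np.ndarray:
    """Slope-dependent threshold: theta = -0.99 s - 40.2 mV.

    ``slope_buffer`` holds per-step membrane increments dv (mV) over the
    trailing 5 ms window; s is their mean divided by dt (mV/ms).  An empty
    buffer yields s = 0 and theta = -40.2 mV.
    """
    if slope_buffer is None or slope_buffer.size == 0:
        s = 0.0
    else:
        s = np.mean(slope_buffer, axis=0) / dt
    return SIMPLE_THETA_GAIN * s + SIMPLE_THETA_INTERCEPT


def theta_inf(v, params: AdaptiveThresholdParams):
    """Steady-state threshold of the adaptive rule (stable softplus)."""
    v = np.asarray(v, dtype=float)
    x = (v - params.v_i) / params.k_i
    softplus = np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))
    return params.alpha * (v - params.v_i) + params.v_T + params.k_alpha * softplus


def threshold_adaptive_step(theta, v, params: AdaptiveThresholdParams, dt: float = 0.1):
    """One forward-Euler step of tau_theta dtheta/dt = theta_inf(v) - theta."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    theta = np.asarray(theta, dtype=float)
    return theta + (dt / params.tau_theta) * (theta_inf(v, params) - theta)


def euler_step(
    state: IzhikevichState,
    a, b, c, d, v_r, v_t,
    i_syn,
    dt: float = 0.1,
    threshold_mode: str = "simple",
    adaptive_params: AdaptiveThresholdParams | None = None,
    check_finite: bool = True,
) -> np.ndarray:
    """Advance the membrane state by one step; returns the spike mask.

    Parameters are scalars or arrays broadcastable to ``state.v``.  The
    reset contract is exact: where a spike fired, the post-step v equals c
    and u has jumped by d.  A neuron cannot fire twice within one step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v, u = state.v, state.u
    dv = (0.04 * (v - v_r) * (v - v_t) - u + i_syn) * dt
    du = (np.asarray(a, float) * (np.asarray(b, float) * (v - v_r) - u)) * dt
    v_new = v + dv
    u_new = u + du

    if state.slope_buffer is not None:
        state.slope_buffer[state.buffer_pos] = dv
        state.buffer_pos = (state.buffer_pos + 1) % state.slope_buffer.shape[0]

    if threshold_mode == "fixed":
        theta = np.broadcast_to(np.asarray(PEAK_MV), v_new.shape)
    elif threshold_mode == "simple":
        theta = np.broadcast_to(threshold_simple(state.slope_buffer, dt), v_new.shape)
    elif threshold_mode == "adaptive":
        if adaptive_params is None:
            raise ValueError("adaptive mode needs AdaptiveThresholdParams")
        theta = threshold_adaptive_step(state.theta, v, adaptive_params, dt)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    state.theta = np.asarray(theta, dtype=float)

    spikes = (v_new >= np.minimum(theta, PEAK_MV)) | (v_new >= PEAK_MV)
    if np.any(spikes):
        c_arr = np.broadcast_to(np.asarray(c, float), v_new.shape)
        d_arr = np.broadcast_to(np.asarray(d, float), v_new.shape)
        v_new = np.where(spikes, c_arr, v_new)
        u_new = np.where(spikes, u_new + d_arr, u_new)

    if check_finite and (not np.isfinite(v_new).all() or not np.isfinite(u_new).all()):
        raise IntegrationBlowupError("membrane state became non-finite")

    state.v = v_new
    state.u = u_new
    return spikes
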