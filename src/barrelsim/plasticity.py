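"""Pairwise STDP for L4->L2/3 and L2/3->L2/3 excitatory synapses.

The timing difference is Delta t = (presynaptic spike time + synaptic
delay) - postsynaptic spike time, in ms: negative Delta t means the
presynaptic spike *arrived before* the postsynaptic neuron fired.

L4->L2/3 rule (three fitted branches; weight-change units a.u.):

    dA = -3.7e-6 dt^2 - 0.0019 dt + 0.77        -250 <= dt <= 0
    dA = 0.5665 dt / 3 - 0.23                       0 < dt <= 3
    dA = -4.7e-7 dt^3 - 0.00028 dt^2
         - 0.022 dt + 1.4                           3 < dt <= 32

dA is 0 outside [-250, 32].  Two readings are exposed:

* ``variant="printed"`` (default) — the branches exactly as fitted, under
  the 1e-6 reading of the quadratic coefficient.  Note that this curve is
  positive over most of the anti-causal side (dt > 1.218 ms), i.e. it
  potentiates there.
* ``variant="repaired"`` — identical magnitudes but the anti-causal side
  (dt > 0) forced non-positive, restoring a conventional depressive
  post-before-pre window.  The whisker-deprivation experiment uses this
  variant by default, since deprivation-induced depression of the
  deprived column's L4->L2/3 projections cannot arise from a rule that
  potentiates anti-causal pairings (see docs/methods.md).

L2/3->L2/3 rule:

    dA = +(0.53/100) exp(-dt/18)                 dt >= 0
    dA = -(0.32/100) exp(+dt/18)                 dt <  0

(the depression branch decays with |dt|; with the exponent as literally
printed it would diverge for dt -> -inf).

Weight updates are additive for potentiation, A <- A + dA, and
multiplicative for depression, A <- A (1 - |dA|), clamped to bounds; the
multiplicative form never drives a weight negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StdpRule",
    "WeightUpdatePolicy",
    "stdp_l4_to_l23",
    "stdp_l23_to_l23",
    "apply_weight_update",
    "pair_spikes",
    "run_deprivation_experiment",
]


def stdp_l4_to_l23(dt_ms, variant: str = "printed") -> np.ndarray:
    """L4->L2/3 pairwise STDP weight change dA(dt)."""
    dt = np.asarray(dt_ms, dtype=float)
    causal = (-3.7e-6 * dt**2 - 0.0019 * dt + 0.77)
    anti_near = 0.5665 * dt / 3.0 - 0.23
    anti_far = -4.7e-7 * dt**3 - 0.00028 * dt**2 - 0.022 * dt + 1.4
    out = np.zeros_like(dt)
    out = np.where((dt >= -250.0) & (dt <= 0.0), causal, out)
    out = np.where((dt > 0.0) & (dt <= 3.0), anti_near, out)
    out = np.where((dt > 3.0) & (dt <= 32.0), anti_far, out)
    if variant == "repaired":
        out = np.where(dt > 0.0, -np.abs(out), out)
    elif variant != "printed":
        raise ValueError(f"unknown variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def stdp_l23_to_l23(dt_ms) -> np.ndarray:
    """L2/3->L2/3 pairwise STDP weight change dA(dt)."""
    dt = np.asarray(dt_ms, dtype=float)
    out = np.where(dt >= 0.0, (0.53 / 100.0) * np.exp(-dt / 18.0),
                   -(0.32 / 100.0) * np.exp(dt / 18.0))
    # window support: beyond ~14 decay constants the change is numerically 0
    out = np.where(np.abs(dt) > 250.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StdpRule:
    """A pairwise STDP rule bound to a pathway and pairing window."""

    pathway: str                      # "L4->L2/3" or "L2/3->L2/3"
    variant: str = "printed"
    window_ms: float = 250.0
    pairing: str = "all_to_all"       # or "nearest"

    def __call__(self, dt_ms) -> np.ndarray:
        if self.pathway == "L4->L2/3":
            return stdp_l4_to_l23(dt_ms, variant=self.variant)
        if self.pathway == "L2/3->L2/3":
            return stdp_l23_to_l23(dt_ms)
        raise ValueError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class WeightUpdatePolicy:
    """Additive potentiation / multiplicative depression with bounds."""

    a_min: float = 0.0
    a_max: float = 5.0

    def __post_init__(self) -> None:
        if self.a_min < 0 or self.a_max <= self.a_min:
            raise ValueError("need 0 <= a_min < a_max")


def apply_weight_update(a, da, policy: WeightUpdatePolicy = WeightUpdatePolicy()):
    """A + dA for dA > 0; A (1 - |dA|) for dA < 0; clamp to bounds."""
    a = np.asarray(a, dtype=float)
    da = np.asarray(da, dtype=float)
    updated = np.where(da >= 0.0, a + da, a * np.clip(1.0 - np.abs(da), 0.0, None))
    out = np.clip(updated, policy.a_min, policy.a_max)
    return float(out) if out.ndim == 0 else out


def pair_spikes(pre_arrivals, post_spikes, window_ms: float = 250.0,
                pairing: str = "all_to_all") -> np.ndarray:
    """Delta t values (pre arrival - post spike) within the pairing window.

    ``all_to_all`` pairs every arrival with every post spike; ``nearest``
    pairs each post spike only with its nearest arrival (for sensitivity
    analysis).
    """
    pre = np.asarray(pre_arrivals, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return np.empty(0)
    if pairing == "all_to_all":
        dts = (pre[:, None] - post[None, :]).ravel()
        return dts[np.abs(dts) <= window_ms]
    if pairing == "nearest":
        idx = np.abs(pre[:, None] - post[None, :]).argmin(axis=0)
        dts = pre[idx] - post
        return dts[np.abs(dts) <= window_ms]
    raise ValueError(f"unknown pairing {pairing!r}")


def run_deprivation_experiment(
    network,
    n_trials: int = 100,
    seed: int = 0,
    variant: str = "repaired",
    pairing: str = "all_to_all",
    policy: WeightUpdatePolicy | None = None,
    trial_duration_ms: float = 60.0,
    v_r: float = -70.0,
    stdp_enabled: bool = True,
    record_history: bool = False,
):
    """Three-column whisker-deprivation STDP experiment (map plasticity).

    ``network`` is an :class:`~barrelsim.engine.Network` with 3 columns;
    the middle column is whisker-deprived and receives surround-evoked
    thalamic input (30% amplitude, +2.5 ms), the lateral columns receive
    principal-whisker input.  After each of ``n_trials`` paired
    stimulations the L4->L2/3 and L2/3->L2/3 excitatory weights are
    updated by the pairwise rules; the returned table reports the mean
    relative weight change grouped by (pathway, pre column status, post
    column status).

    Returns ``(table, details)`` where details carries the final weights
    and, optionally, the per-trial group means.
    """
    from . import engine as _engine  # runtime import to avoid a cycle

    if network.population.geometry.n_columns != 3:
        raise ValueError("the deprivation experiment needs a 3-column network")
    plastic = _plastic_edge_masks(network)
    conn = network.connections
    any_plastic = np.zeros(conn.n_edges, dtype=bool)
    for mask in plastic.values():
        any_plastic |= mask
    # bound weights at twice the largest initial plastic weight so
    # potentiation saturates instead of destabilizing the network
    if policy is None:
        w_cap = float(conn.weight[any_plastic].max()) if any_plastic.any() else 1.0
        policy = WeightUpdatePolicy(a_max=2.0 * w_cap)
    rng = np.random.default_rng(seed)

    w0 = conn.weight.astype(float).copy()

    rules = {
        "L4->L2/3": StdpRule("L4->L2/3", variant=variant, pairing=pairing),
        "L2/3->L2/3": StdpRule("L2/3->L2/3", pairing=pairing),
    }
    pre_status, post_status = network.edge_column_status()
    dt = network.dt
    history = []

    psth = network.stimulus_psth
    for trial in range(n_trials):
        thal_trains = _engine.deprivation_thalamic_trial(
            network, psth, rng=np.random.default_rng(rng.integers(2**31 - 1))
        )
        record = _engine.run_simulation(
            network,
            thalamic_trains=thal_trains,
            duration_ms=trial_duration_ms,
            seed=int(rng.integers(2**31 - 1)),
            v_r=v_r,
        )
        if stdp_enabled:
            spikes_by_neuron = record.spikes_by_neuron()
            active = np.zeros(network.n_total, dtype=bool)
            active[list(spikes_by_neuron)] = True
            for name, mask in plastic.items():
                rule = rules[name]
                edges = np.nonzero(mask & active[conn.pre] & active[conn.post])[0]
                for e in edges:
                    arrivals = spikes_by_neuron[int(conn.pre[e])] + conn.delay_steps[e] * dt
                    dts = pair_spikes(arrivals, spikes_by_neuron[int(conn.post[e])],
                                      rule.window_ms, rule.pairing)
                    if dts.size == 0:
                        continue
                    w = conn.weight[e]
                    for da in rule(dts):
                        w = apply_weight_update(w, da, policy)
                    conn.weight[e] = w
        if record_history:
            history.append(
                _group_weight_change(conn, w0, plastic, pre_status, post_status)
                .assign(trial=trial)
            )

    table = _group_weight_change(conn, w0, plastic, pre_status, post_status)
    details = {"initial_weight": w0, "final_weight": conn.weight.copy()}
    if record_history:
        details["history"] = pd.concat(history, ignore_index=True)
    return table, details


def _plastic_edge_masks(network) -> dict[str, np.ndarray]:
    """Excitatory L4->L2/3 and L2/3->L2/3 edges eligible for STDP."""
    pop = network.population
    conn = network.connections
    n_thal = network.n_thalamic
    cortical = (conn.pre >= n_thal) & (conn.post >= n_thal)
    pre_idx = np.clip(conn.pre - n_thal, 0, pop.n_neurons - 1)
    post_idx = np.clip(conn.post - n_thal, 0, pop.n_neurons - 1)
    pre_l4e = (pop.layer[pre_idx] == "L4") & (pop.sign[pre_idx] == 1)
    pre_l23e = (pop.layer[pre_idx] == "L2/3") & (pop.sign[pre_idx] == 1)
    post_l23e = (pop.layer[post_idx] == "L2/3") & (pop.sign[post_idx] == 1)
    return {
        "L4->L2/3": cortical & pre_l4e & post_l23e,
        "L2/3->L2/3": cortical & pre_l23e & post_l23e,
    }


def _group_weight_change(conn, w0, plastic, pre_status, post_status) -> pd.DataFrame:
    out = []
    for name, mask in plastic.items():
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        rel = (conn.weight[idx] - w0[idx]) / np.where(w0[idx] > 0, w0[idx], 1.0)
        out.append(
            pd.DataFrame(
                {
                    "pathway": name,
                    "pre_status": pre_status[idx],
                    "post_status": post_status[idx],
                    "rel_change": rel,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["pathway", "pre_status", "post_status", "mean_rel_change", "n_edges"]
        )
    return (
        pd.concat(out, ignore_index=True)
        .groupby(["pathway", "pre_status", "post_status"], as_index=False)
        .agg(mean_rel_change=("rel_change", "mean"), n_edges=("rel_change", "size"))
    )
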