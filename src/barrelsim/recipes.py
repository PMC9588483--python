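"""The four packaged experiment recipes.

* ``state_sweep`` — single-deflection trials across membrane states
  (-80/-70/-60 mV): PSTHs, peak latencies and the spikes/stimulus table.
* ``variability`` — the two thalamic-variability conditions (fresh
  Poisson draw per trial vs. one frozen realization repeated), PSTHs and
  per-neuron spike-count variance.
* ``deprivation`` — the 3-column whisker-deprivation STDP experiment and
  its weight-change table.
* ``whisking_imaging`` — synthetic freely-whisking input through
  filter-and-fire thalamic encoders, the cortical response, and the
  calcium-fluorescence rendering with before/after-touch frame
  differences.

Every recipe writes CSV artifacts plus a ``manifest.json`` with the
config hash, seeds and package version, sufficient to reproduce the run
bit-exactly in the single-threaded reference mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, engine, imaging, plasticity, thalamus
from .config import ExperimentRecipe, config_hash

__all__ = ["run_recipe"]


def _write_manifest(out: Path, cfg: ExperimentRecipe, extra: dict | None = None) -> None:
    manifest = {
        "recipe": cfg.recipe,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
    }
    manifest.update(extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _build(cfg: ExperimentRecipe, n_columns: int | None = None) -> engine.Network:
    net = cfg.network
    return engine.build_network(
        n_columns=n_columns if n_columns is not None else net.n_columns,
        scale=net.scale,
        seed=cfg.seed,
        dt=cfg.simulation.dt,
        compensate_weights=net.compensate_weights,
        n_thal_per_column=net.n_thal_per_column,
        threshold_mode=net.threshold_mode,
    )


def run_recipe(cfg: ExperimentRecipe, out_dir) -> Path:
    """Execute a recipe and return the artifact directory."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "state_sweep": _run_state_sweep,
        "variability": _run_variability,
        "deprivation": _run_deprivation,
        "whisking_imaging": _run_whisking_imaging,
    }[cfg.recipe]
    extra = runner(cfg, out) or {}
    _write_manifest(out, cfg, extra)
    return out


def _run_state_sweep(cfg: ExperimentRecipe, out: Path) -> dict:
    network = _build(cfg)
    blocks = cfg.state_sweep
    records_by_state = {}
    psth_rows = []
    for i, state in enumerate(blocks.states_mV):
        recs = engine.run_stimulus_trials(
            network, blocks.n_trials, v_r=state, seed=cfg.seed + 1000 * i,
            duration_ms=cfg.simulation.duration_ms,
        )
        records_by_state[state] = recs
        for sel_name, ids in _selections(network).items():
            merged = _merge_records(recs)
            psth = engine.compute_psth(merged, ids, bin_ms=1.0)
            for t, r in zip(psth.bin_edges[:-1], psth.rates):
                psth_rows.append({"state_mV": state, "population": sel_name,
                                  "t_ms": t, "rate_hz": r})
    pd.DataFrame(psth_rows).to_csv(out / "psth.csv", index=False)
    table = engine.firing_rate_by_state(records_by_state, network)
    table.to_csv(out / "spikes_per_stimulus.csv", index=False)
    return {"n_trials": blocks.n_trials, "states_mV": list(blocks.states_mV)}


def _run_variability(cfg: ExperimentRecipe, out: Path) -> dict:
    network = _build(cfg)
    blk = cfg.variability
    rows = []
    for cond, repeat in (("poisson_per_trial", False), ("repeated_realization", True)):
        recs = engine.run_stimulus_trials(
            network, blk.n_trials, v_r=blk.state_mV, seed=cfg.seed,
            duration_ms=cfg.simulation.duration_ms, repeat_realization=repeat,
        )
        counts = np.stack([
            np.bincount(r.cortical()[0] - network.n_thalamic,
                        minlength=network.n_cortical)
            for r in recs
        ])
        rows.append({
            "condition": cond,
            "mean_count": float(counts.mean()),
            "across_trial_var": float(counts.var(axis=0).mean()),
        })
        _merge_records(recs).to_csv(out / f"spikes_{cond}.csv")
    pd.DataFrame(rows).to_csv(out / "variability_summary.csv", index=False)
    return {"n_trials": blk.n_trials}


def _run_deprivation(cfg: ExperimentRecipe, out: Path) -> dict:
    network = _build(cfg, n_columns=3)
    blk = cfg.deprivation
    table, details = plasticity.run_deprivation_experiment(
        network, n_trials=blk.n_trials, seed=cfg.seed, variant=blk.variant,
        pairing=blk.pairing, trial_duration_ms=blk.trial_duration_ms,
    )
    table.to_csv(out / "weight_change.csv", index=False)
    return {"n_trials": blk.n_trials, "variant": blk.variant}


def _run_whisking_imaging(cfg: ExperimentRecipe, out: Path) -> dict:
    blk = cfg.whisking_imaging
    network = _build(cfg)
    network.threshold_mode = "adaptive"
    trace = thalamus.generate_synthetic_whisking(
        duration_ms=blk.duration_ms, whisk_freq_hz=blk.whisk_freq_hz,
        whisk_amp_deg=blk.whisk_amp_deg, touch_times_ms=blk.touch_times_ms,
        touch_curvature_amp=blk.touch_curvature_amp, seed=cfg.seed,
    )
    trace.to_frame().to_csv(out / "whisker_trace.csv", index=False)
    encoders = thalamus.random_filter_neurons(
        network.n_thalamic, dt_ms=trace.dt_ms, seed=cfg.seed + 1,
    )
    rng = np.random.default_rng(cfg.seed + 2)
    trains = [
        thalamus.filter_and_fire(trace, enc, seed=int(rng.integers(2**31 - 1)))
        for enc in encoders
    ]
    record = engine.run_simulation(
        network, trains, duration_ms=blk.duration_ms, seed=cfg.seed + 3,
        v_r=blk.state_mV, threshold_mode="adaptive",
    )
    record.to_csv(out / "spikes.csv")
    spikes = record.spikes_by_neuron()
    l23_ids = network.cortical_global_ids(network.population.select(layer="L2/3"))
    trains_l23 = [spikes.get(int(i), np.empty(0)) for i in l23_ids]
    frame_times, C, L = imaging.simulate_fluorescence(
        trains_l23, blk.duration_ms, seed=cfg.seed + 4,
    )
    imaging.traces_to_frame(frame_times, L).to_csv(out / "fluorescence.csv", index=False)
    if blk.touch_times_ms:
        touch_frame = int(blk.touch_times_ms[0] // (1000.0 / 7.0))
        touch_frame = min(max(touch_frame, 1), frame_times.size - 2)
        delta, counts, edges = imaging.frame_difference(L, touch_frame)
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "count": counts}).to_csv(out / "touch_response_hist.csv", index=False)
    return {"n_thalamic": network.n_thalamic}


def _selections(network: engine.Network) -> dict[str, np.ndarray]:
    pop = network.population
    sel = {
        "thalamus": np.arange(network.n_thalamic),
        "L4_exc": network.cortical_global_ids(pop.select(layer="L4", sign=1)),
        "L4_inh": network.cortical_global_ids(pop.select(layer="L4", sign=-1)),
        "L23_exc": network.cortical_global_ids(pop.select(layer="L2/3", sign=1)),
        "L23_inh": network.cortical_global_ids(pop.select(layer="L2/3", sign=-1)),
    }
    return sel


def _merge_records(records: list[engine.SpikeRecord]) -> engine.SpikeRecord:
    """Pool trial records into one (analysis convenience; times unchanged)."""
    return engine.SpikeRecord(
        neuron_id=np.concatenate([r.neuron_id for r in records]),
        t_ms=np.concatenate([r.t_ms for r in records]),
        n_thalamic=records[0].n_thalamic,
        n_total=records[0].n_total,
        duration_ms=records[0].duration_ms,
        dt=records[0].dt,
    )
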