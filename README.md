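# barrelsim

A biologically constrained spiking-network model of the granular (L4)
and supragranular (L2/3) layers of a rodent barrel-cortex column, with
thalamic (VPM) input, spike-timing-dependent plasticity, and a calcium
imaging forward model.

`barrelsim` is for computational neuroscientists who want a
desktop-scale, fully seeded reconstruction of the first stages of
whisker-touch processing: how a single deflection propagates from VPM
through L4 to L2/3, how the cortical membrane state (up/down states,
modeled as a common resting potential of −80/−70/−60 mV) gates that
propagation, how whisker deprivation reorganizes L4→L2/3 synapses under
pairwise STDP, and what the resulting activity would look like through a
7 Hz calcium imaging experiment.

## The model

Neurons are quadratic two-variable (Izhikevich-type) point neurons,

    dv/dt = 0.04 (v − v_r)(v − v_t) − u + I,
    du/dt = a (b (v − v_r) − u),       spike: v ← c, u ← u + d,

integrated by forward Euler at 0.1 ms, with a history-dependent spike
threshold: either θ = −0.99 s − 40.2 mV, where s is the mean dv/dt over
the trailing 5 ms (fast-rising EPSPs lower the threshold), or a
first-order threshold ODE θ∞(v) = α(v − v_i) + v_T + k_α log(1 +
e^{(v−v_i)/k_i}). Thirteen cortical cell types (9 in L2/3, 4 in L4) are
placed in a 640 × 300 × 300 µm column; connectivity follows Peter's
rule: the connection probability of a pair is proportional to the
overlap integral of the presynaptic axonal and postsynaptic dendritic
3-D Gaussian fields, P_ij = k·I_ij, with k calibrated per type pair so
the mean probability within 100 µm matches measured values. Synapses
are double-exponential current kernels matched to PSP rise time and
half-width, with short-term plasticity (dx/dt = (1 − x)/τ_x, x ← p x on
a spike), stochastic failures, amplitude CV, and conduction delays at
190 µm/ms. Layer borders come from Gaussian fits g(z) = c1 + c2
e^{−(z−z0)²/2σ²} to density profiles, with z_lim = z0 ± σ√(2 ln 2).

Thalamic input is either PSTH-constrained inhomogeneous Poisson firing
(single-deflection experiments) or a bank of filter-and-fire encoders
driven by whisker angle and curvature (freely-whisking experiments);
surround whiskers receive the stimulus at 30% amplitude, delayed
2.5 ms. A synthetic whisking generator produces angle/curvature traces
at 1 kHz with rhythmic whisking and touch-evoked curvature transients.

See `docs/methods.md` for the full model description, the provenance of
every default, and known limitations.

## Worked example

```python
import numpy as np
from barrelsim import engine

net = engine.build_network(n_columns=1, scale=0.15, seed=0)

for v_r in (-80.0, -70.0, -60.0):
    recs = engine.run_stimulus_trials(net, 10, v_r=v_r, seed=1000,
                                      duration_ms=60.0)
    table = engine.firing_rate_by_state({v_r: recs}, net,
                                        window_ms=(0.0, 60.0))
    row = table.set_index("class")["mean"]
    print(f"v_r = {v_r:.0f} mV: L4 exc {row['L4 excitatory']:.3f}, "
          f"L4 inh {row['L4 inhibitory']:.3f}, "
          f"L2/3 exc {row['L2/3 excitatory']:.3f} spikes/stimulus")
```

prints

```
v_r = -80 mV: L4 exc 0.017, L4 inh 0.422, L2/3 exc 0.000 spikes/stimulus
v_r = -70 mV: L4 exc 0.111, L4 inh 0.896, L2/3 exc 0.019 spikes/stimulus
v_r = -60 mV: L4 exc 0.264, L4 inh 1.422, L2/3 exc 0.235 spikes/stimulus
```

Excitatory firing is sparse and grows with depolarization; inhibitory
cells respond more reliably; and in the hyperpolarized state L2/3 is
silent — the supragranular network decouples from bottom-up input.
Population PSTH peak latencies from the same records order as
thalamus (6.5 ms) → L4 (9.5 ms) → L2/3 (13.5 ms):

```python
ids = net.cortical_global_ids(net.population.select(layer="L4"))
psth = engine.compute_psth(recs[0], ids, bin_ms=1.0)
print(engine.peak_latency(psth))
```

The deprivation experiment (three columns, middle column deprived of
its principal whisker) runs as

```python
from barrelsim import plasticity
net3 = engine.build_network(n_columns=3, scale=0.12, seed=100)
table, _ = plasticity.run_deprivation_experiment(net3, n_trials=100, seed=0)
```

and returns the mean relative weight change per pathway and column
status; with the default rule variant the spared columns' L4→L2/3
projections potentiate (≈ +0.2) while the deprived column's depress
(≈ −0.35) within 100 trials.

## Command line

```bash
barrelsim build-network   --config cfg.yaml --out out/   # population + edge tables
barrelsim simulate        --config cfg.yaml --out out/   # membrane-state sweep
barrelsim stdp-experiment --config cfg.yaml --out out/   # 3-column deprivation
barrelsim whisking-demo   --seed 3 --out out/            # synthetic whisking + encoders
barrelsim imaging-demo    --config cfg.yaml --out out/   # whisking + calcium imaging
barrelsim analyze         --spikes spikes.csv --out psth.csv
```

Configs are YAML with strict key checking; every run writes a
`manifest.json` (config hash, seed, version) sufficient to reproduce it
bit-exactly.

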