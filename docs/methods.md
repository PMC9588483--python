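# Methods

`barrelsim` reconstructs the granular (L4) and supragranular (L2/3)
portions of a rodent barrel-cortex column as a spiking network driven by
thalamic (VPM) input, together with the analysis readouts used to
characterize such models: population PSTHs, peak latencies,
state-dependent spikes/stimulus tables, spike-triggered presynaptic
maps, an STDP whisker-deprivation experiment, and a calcium-fluorescence
forward model. This note documents the model equations, the parameters
that matter, the provenance of every default, and the limits of what the
shipped synthetic inputs can demonstrate.

## Anatomy

The modeled slab is 640 µm deep and 300 × 300 µm wide per column: L2/3
(0–430 µm depth) above L4 (430–640 µm). z is depth from the top of the
slab, increasing downward. Layer borders in density profiles are found
by fitting

    g(z) = c1 + c2 exp(-(z - z0)^2 / (2 sigma^2))

to a NeuN+ density-vs-depth table (nonlinear least squares via
`scipy.optimize.curve_fit`, data-driven initial values: minimum density
for `c1`, range for `c2`, argmax depth for `z0`) and taking the
half-maximum depths `z_lim = z0 ± sigma sqrt(2 ln 2)`. A profile whose
bump amplitude is indistinguishable from zero raises a
degenerate-profile error rather than returning meaningless borders.

Thirteen cortical cell types are registered — 9 in L2/3 (L2 and L3
pyramids plus 7 inhibitory classes) and 4 in L4 (spiny stellates, star
pyramids, PV+ fast-spiking, PV− low-threshold spiking). Default
per-type counts anchor L4 at ~1600 neurons per full-scale column and
L2/3 at ~1930 with a ~12% inhibitory fraction; they are stand-in
approximations, overridable via config. Placement is uniform in 3-D
within the (layer, column) slab; a depth-profile-weighted mode is a
possible extension but the uniform law is the default because no
sub-layer position law is constrained by the data the model is built
from.

## Membrane dynamics

Each neuron follows the quadratic two-variable model

    dv/dt = 0.04 (v - v_r)(v - v_t) - u + I
    du/dt = a (b (v - v_r) - u)

integrated by forward Euler at dt = 0.1 ms, with reset v ← c, u ← u + d
at a spike. The reset condition is the standard peak condition v ≥ 30 mV
(the inequality is sometimes printed reversed in the literature this
model family derives from; the reversed form never fires). Spike
emission additionally uses a history-dependent threshold θ in two
selectable forms:

* **simple** (default for stimulus-evoked experiments):
  θ(t) = −0.99 s − 40.2 mV, where s is the mean dv/dt (mV/ms) over the
  trailing 5 ms (50 steps). s is computed from the total membrane
  derivative, not a per-synapse decomposition, since only the compound
  depolarization history is defined in a point neuron. Faster-rising
  depolarizations therefore lower the threshold.
* **adaptive** (default for the freely-whisking pipeline):
  τ_θ dθ/dt = θ∞(v) − θ with
  θ∞(v) = α(v − v_i) + v_T + k_α log(1 + exp((v − v_i)/k_i)),
  evaluated with a numerically stable softplus. Default constants
  (τ_θ = 5 ms, α = 0.2, v_i = −60, v_T = −45, k_α = 5, k_i = 2 mV) are
  stand-ins of the published per-type fits, which are not reproduced in
  any source available to this package.

A spike is emitted when v crosses min(θ, 30 mV) from below; the
suprathreshold upstroke is not modeled in detail. Neurons cannot fire
twice within one step. Initial conditions are v ~ Normal(state mean,
1.3 mV), u = b (v − v_r). The *membrane state* (−80 / −70 / −60 mV)
sets both the common v_r and the initial-v mean, standing in for
cortical down, intermediate and up states.

Forward Euler at 0.1 ms carries an O(dt) period bias of ~0.2–0.3% in
tonic-firing regimes, i.e. a few ms of accumulated phase per second of
sustained spiking; against a 10×-finer reference the per-spike budget is
~0.2 ms. In the input-driven regime the network actually operates in
(spikes locked to synaptic events), spike times agree with a dt/10
reference to well under 1 ms because phase errors cannot accumulate.
The convergence tests check both statements separately.

## Connectivity

Axonal and dendritic arbors are 3-D Gaussians attached to each soma
(per-type offsets and widths; stand-in table). The overlap index

    I_ij = ∫ A_i D_j dV  over the support holding 99.9% of D_j

is evaluated in closed form (Gaussian product integral; per-axis
variance σ_A² + σ_D²), with the 99.9% truncation applied as a
multiplicative mass correction — the exact Mahalanobis-ball restriction
changes I by < 0.1% for any realistic geometry, and a brute-force grid
quadrature mode exists for validation (the oracle test requires
closed-form/quadrature agreement within 0.5%).

Connection probability is P_ij = k · I_ij with k calibrated per type
pair so that the mean P over same-column pairs within 100 µm inter-soma
distance matches the target pairwise probability; P is clipped to [0,1]
(clipping events are counted on the network object). For thalamocortical
pathways the calibration distance is tangential only, because thalamic
somata sit at a virtual depth (900 µm) below the slab so that the
distance-derived conduction delays (~2 ms to L4) are realistic. In
sparse scaled-down populations a type pair can have no same-column pair
within 100 µm; the builder then widens the calibration radius in steps
(200, 400, 800 µm) rather than failing. Edges are independent Bernoulli
draws; inter-column connections follow the same rules and are weaker
only because the somata are farther apart. Conduction delay is
distance / 190 µm/ms, floored at one integration step.

## Synapses

PSCs are double-exponential kernels normalized to unit peak; (τ_rise,
τ_decay) are fit numerically (nested Brent root-finding inside a
least-squares loop) so that the kernel reproduces the pathway's 10–90%
rise time and half-width — the statistics synaptic physiology reports —
to better than 1%. The degenerate τ_rise → τ_decay limit is the alpha
function. Events are injected as currents into dv/dt; the PSP-amplitude
weights (mV) are converted to current amplitudes with a factor computed
from the linearized membrane (relaxation rate 0.04 (v_t − v_r) ≈
1.2/ms at rest), so a unit weight produces a ~1 mV peak depolarization
at rest. This matches the additive appearance of I in the membrane
equation; conductance-based synapses with reversal potentials are out
of scope.

Short-term plasticity is a single resource x per synapse relaxing to 1
with τ_x (150 ms for excitatory and depressing inhibitory synapses,
100 ms for facilitating ones) and jumping x ← p x at each presynaptic
spike; the delivered amplitude uses the post-jump x, so a paired pulse
at interval Δ has absolute second-peak factor p(1 − (1 − p)e^{−Δ/τ_x}).
The resting level in the resource ODE is the constant 1 — any other
reading of the relaxation target makes the dynamics diverge. Failures
are independent per-spike Bernoulli deletions at a fixed pathway rate
(failed events still consume STP resource); amplitude CV is per-event
multiplicative Gaussian jitter truncated at zero.

### Default tables and their calibration

All pathway parameters (connection probabilities within 100 µm, PSP
shape statistics, failure rates, STP factors) ship as stand-in tables in
`defaults.py`. Connection probabilities and kinetics follow typical
juvenile-rodent slice values. PSP amplitudes required calibration: with
raw slice amplitudes the model column saturates, because the
threshold-crossing spike rule has no refractory period, so any neuron
under sustained suprathreshold current fires once per rise time (~kHz).
The calibrated table (thalamocortical drive strong and fast; cortical
excitation onto interneurons weak — they already receive massive
convergence; inhibition strong; L4→L2/3 feedforward doubled) and an
after-spike jump d = 8 for the inhibitory classes place the column at
the physiological operating point: sparse excitatory firing (~0.05 →
0.4 spikes/stimulus from the hyperpolarized to the depolarized state),
reliable but bounded inhibitory firing (~0.3 → 1.1), inhibitory onset
preceding excitatory within each layer, and complete silence of L2/3
excitatory cells in the hyperpolarized state. Adapting d to match
observed firing rates is the same calibration step the model family
this package implements has always used.

## Thalamic input

Each column has one VPM barreloid (default 200 neurons full-scale, ~1/18
of two barrels' neuron count; the filter-and-fire experiment uses 200).
Two encoders exist:

* **PSTH-constrained Poisson** — all barreloid neurons share a
  population PSTH and draw independent inhomogeneous Poisson trains per
  trial (per-bin Poisson counts, uniform placement within bins). The
  shipped single-deflection PSTH is a synthetic stand-in: baseline
  0.5 Hz, gamma-shaped onset at 5 ms, peak near 7 ms, integrating to
  1.5 spikes/stimulus/neuron. A repeat mode freezes one realization
  across trials (thalamic Fano factor exactly 0) for the
  response-variability experiment.
* **Filter-and-fire** — each neuron filters a mixture (weight ∈ [0,1])
  of the z-scored whisker angle and curvature channels with a biphasic
  difference-of-alpha kernel (randomized widths 2–8 ms, latency 1–6 ms,
  polarity), passes it through a saturating sigmoid (randomized gain and
  offset, max 200 Hz), and spikes as an inhomogeneous Poisson process
  with a 1 ms absolute refractory period. The original filter
  parametrization is external to the sources available here; the bank is
  fully configurable.

Surround (non-principal) whiskers receive the principal stimulus scaled
to 30% amplitude and delayed 2.5 ms; the transform is linear and
composes (two applications give 9% and +5 ms).

The synthetic whisking generator emulates head-fixed freely-whisking
recordings at 1 kHz: angle = slow set-point drift (0.4 Hz, ±5°) +
rhythmic whisking (default 8 Hz, 15° amplitude) + white noise;
curvature = baseline + touch transients (2 ms rise, 25 ms decay,
default peak 0.05 mm⁻¹) at configured times. It reproduces the channel
structure, sampling and magnitudes of such recordings but none of their
kinematic irregularity (variable whisk cycles, pump events, slip-stick
micromotions); network tests driven by it therefore demonstrate correct
transduction and encoding mechanics, not performance on real behavior.

## STDP and the deprivation experiment

Δt = (presynaptic spike time + conduction delay) − postsynaptic spike
time, in ms; negative Δt means the input arrived before the
postsynaptic spike. The L4→L2/3 rule is the printed three-branch fit
(−3.7·10⁻⁶ Δt² − 0.0019 Δt + 0.77 on [−250, 0]; 0.5665 Δt/3 − 0.23 on
(0, 3]; −4.7·10⁻⁷ Δt³ − 0.00028 Δt² − 0.022 Δt + 1.4 on (3, 32]; zero
outside), the L2/3–L2/3 rule is +0.0053 e^{−Δt/18} for Δt ≥ 0 and
−0.0032 e^{+Δt/18} for Δt < 0 (the depression branch must decay with
|Δt| to be integrable). Updates are additive for potentiation
(A ← A + dA) and multiplicative for depression (A ← A(1 − |dA|), which
cannot produce a negative weight), clamped to bounds; pairing is
all-to-all within a 250 ms window by default with a nearest-neighbor
mode for sensitivity analysis.

Two readings of the L4→L2/3 rule are selectable. As printed
(`variant="printed"`), the anti-causal side is *positive* almost
everywhere (only Δt ∈ (0, 1.22] depresses; the cubic branch jumps to
+1.33 at Δt = 3⁺), so the rule potentiates nearly every pairing — a
shape that cannot produce depression of a feedforward pathway under any
timing statistics in which inputs and spikes remain loosely coupled.
Because the experimental phenomenon this rule exists to model includes
depression of the deprived column's L4→L2/3 projections, the experiment
driver defaults to `variant="repaired"`: identical magnitudes with the
anti-causal side forced non-positive. The rule functions themselves
default to the printed form, and custom coefficients can be supplied
through the config.

The deprivation experiment wires three columns; the middle column
receives surround-evoked thalamic input (30%, +2.5 ms), the lateral
columns principal-whisker input. After each of (default) 100
stimulation trials, all excitatory L4→L2/3 and L2/3→L2/3 synapses are
updated from the trial's spike pairings; weights are bounded at twice
the largest initial *plastic* weight so potentiation saturates instead
of destabilizing the network. The trial membrane state defaults to
−70 mV — the intermediate state, where firing is sparse and
input-driven; in the depolarized state recurrent activity decouples
spiking from the stimulus and washes out the pairing structure that
deprivation is supposed to alter. The readout is the mean relative
weight change grouped by pathway and the deprivation status of the
pre- and postsynaptic columns.

Measured behavior over 100 trials (5 wiring/trial seeds, scaled
columns): with the repaired rule the spared columns' L4→L2/3
projections potentiate (+5% to +26% mean relative change) while the
deprived column's depress (−31% to −46%) — sparse, loosely coupled
deprived-column activity accumulates compounding multiplicative
depression, while the bounded additive potentiation of its occasional
causal pairings saturates. With the rule exactly as printed the same
protocol potentiates every pathway nearly uniformly (~+0.65) and the
spared/deprived contrast disappears, because the printed anti-causal
branches are positive beyond Δt = 1.22 ms. This is the concrete reason
the experiment driver defaults to the repaired variant.

## Calcium imaging forward model

Per frame (Δt_C = 1000/7 ≈ 143 ms, i.e. 7 Hz):

    Δ[C] = −(Δt_C/τ_C)([C] − [C]_b) + A_C N_spikes + σ_C √(Δt_C) η_C
    L = α [C] + β + σ_f η_f

with τ_C = 500 ms, [C]_b = 0.1, A_C = 5 per spike, σ_C = 1, α = 1,
β = 0, σ_f = 1 (all a.u.). Spikes are binned per frame before applying
A_C·N. The luminescence line is written as an increment in the source
model; accumulating that increment would integrate the calcium trace
twice, so the default assigns L each frame (`luminescence_mode=
"assign"`); the literal accumulation is available behind the flag. The
noise-free impulse response is exactly [C]_b + A_C λ^k with
λ = 1 − Δt_C/τ_C, checked to 1e-12. The touch readout is the per-neuron
difference between the frames one after and one before the touch, plus
its population histogram.

## Problem sizes, determinism, degenerate inputs

* Network-level tests and the packaged experiments run scaled-down
  columns (scale 0.12–0.2 of the full counts, weights multiplied by
  1/scale so the compound drive per neuron is preserved; the inflated
  single-event amplitudes raise fluctuation-driven variability, which is
  the usual cost of down-scaling). Full-scale single columns build in a
  few seconds and simulate at roughly 1 s per 100 ms trial on one core.
* Every random stage (placement, parameter draws, wiring, thalamic
  draws, failures, jitter, initial conditions) derives from explicit
  seeds; identical (config, seed) reproduce records bit-exactly in the
  single-threaded reference implementation.
* Event-queue determinism: deliveries are grouped per integration step;
  within a step, contributions sum, so ordering cannot change results.
* Degenerate inputs raise typed errors: flat density profiles, empty
  PSTH selections, all-zero PSTHs (undefined latency), no-trigger
  presynaptic maps, zero-volume slabs with nonzero counts, calibration
  with no in-radius pairs, infeasible PSC shape targets.

## Known limitations

* No refractory period, conductance synapses, dendrites, gap junctions,
  history-dependent failures, or infragranular layers (L5/6); the POM
  pathway and direct motor-cortex whisker modulation are not modeled.
* All supplementary-table-derived parameters are stand-ins; absolute
  rates and latencies are calibrated, not derived.
* The synthetic whisking stimulus and the synthetic deflection PSTH are
  surrogates; conclusions about real recorded data require supplying
  real traces/PSTHs through the documented CSV interfaces.
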