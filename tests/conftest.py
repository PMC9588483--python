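import numpy as np
import pytest

from barrelsim import engine


@pytest.fixture(scope="session")
def small_network():
    """A single scaled-down column shared across engine-level tests."""
    return engine.build_network(n_columns=1, scale=0.15, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_two_neuron_network(
    weight=1.0,
    delay_steps=5,
    failure=0.0,
    cv=0.0,
    stp_p=1.0,
    sign=1,
    n_thal=1,
):
    """Minimal hand-built network: one thalamic source driving one cortical
    excitatory cell (plus an optional disconnected second cortical cell),
    for controlled causality/determinism checks."""
    from barrelsim.anatomy import CellTypeSpec, ColumnGeometry, NeuronPopulation
    from barrelsim.connectivity import ConnectionSet
    from barrelsim.synapses import fit_double_exponential

    spec = CellTypeSpec(
        name="L4_spiny_stellate", layer="L4", sign=1, count=2,
        izh_mean=(0.02, 0.2, -65.0, 8.0), izh_sd=(0, 0, 0, 0),
    )
    geom = ColumnGeometry()
    n = 2
    pop = NeuronPopulation(
        registry=[spec], geometry=geom,
        type_index=np.zeros(n, dtype=int), column=np.zeros(n, dtype=int),
        x=np.array([150.0, 160.0]), y=np.array([150.0, 150.0]),
        z=np.array([500.0, 500.0]),
        a=np.full(n, 0.02), b=np.full(n, 0.2), c=np.full(n, -65.0),
        d=np.full(n, 8.0), v_r=np.full(n, -70.0), v_t=np.full(n, -40.0),
    )
    kernel, _ = fit_double_exponential(1.0, 0.6, 4.0, sign=sign)
    conn = ConnectionSet(
        pre=np.array([0]), post=np.array([n_thal + 0]),
        weight=np.array([float(weight)]),
        delay_steps=np.array([delay_steps]),
        stp_p=np.array([stp_p]), stp_tau=np.array([150.0]),
        failure=np.array([float(failure)]), cv=np.array([float(cv)]),
        kernel_id=np.array([0]), sign=np.array([sign]),
        pathway_id=np.array([0]), pathway_names=["VPM->L4_spiny_stellate"],
    )
    net = engine.Network(
        population=pop, connections=conn, kernels=[kernel],
        kernel_current_scale=np.array([engine._membrane_psp_factor(kernel, 0.1) ** -1]),
        thal_column=np.zeros(n_thal, dtype=int),
        thal_pos=np.tile([150.0, 150.0, 900.0], (n_thal, 1)),
    )
    return net
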