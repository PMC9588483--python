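"""Default parameter tables for the barrel-column model.

The published model draws its per-type Izhikevich parameters, adaptive
threshold constants, axon/dendrite Gaussian fits, pairwise connection
probabilities and synapse statistics from supplementary tables that are
not reproduced in the main text.  The tables below are explicit
stand-ins: Izhikevich parameters come from the canonical cell classes
(regular spiking, fast spiking, low-threshold spiking, bursting),
connection probabilities and PSP statistics from typical slice
measurements in juvenile rodent barrel cortex, and projection fields
from the qualitative laminar targeting of each class.  Everything here
can be overridden through the config layer.

Cell-type naming: 13 cortical types — L2/3: L2 pyramidal, L3 pyramidal,
plus 7 inhibitory classes (PV+ fast-spiking, PV+ bursting, SST+
Martinotti, neurogliaform, CR+ bipolar, CR+/VIP+ multipolar, VIP+/CR−);
L4: spiny stellate, star pyramidal, PV+ fast-spiking, PV− low-threshold
spiking.
"""

from __future__ import annotations

import numpy as np

from .anatomy import CellTypeSpec, ColumnGeometry
from .connectivity import ProjectionField
from .dynamics import AdaptiveThresholdParams

__all__ = [
    "default_registry",
    "default_geometry",
    "projection_fields",
    "vpm_axon_field",
    "thalamic_dendrite_field",
    "connection_probability",
    "synapse_params",
    "group_of",
    "adaptive_threshold_params",
    "CELL_GROUPS",
    "N_PER_BARRELOID",
    "THALAMIC_SOMA_DEPTH",
]

# --------------------------------------------------------------------------
# cell classes

# canonical Izhikevich parameter sets (a, b, c); the after-spike jump d is
# adapted so per-stimulus spike counts fall in the experimentally reported
# range (the original model adapted d the same way)
_RS = (0.02, 0.2, -65.0, 8.0)     # regular spiking (excitatory)
_FS = (0.1, 0.2, -65.0, 8.0)      # fast spiking (PV+)
_LTS = (0.02, 0.25, -65.0, 8.0)   # low-threshold spiking (SST+, PV-)
_BURST = (0.02, 0.2, -55.0, 8.0)  # bursting interneuron (PV+ bursting)

_SD_FRAC = 0.1   # parameter heterogeneity: sd = 10% of |mean|


def _sd(mean):
    return tuple(max(abs(m) * _SD_FRAC, 1e-4) for m in mean)


#: per-type neuron counts for a full-scale column (stand-in approximations
#: anchored to L4 ~ 1600 neurons and excitatory:inhibitory ~ 8:1)
_TYPE_TABLE = [
    # name,                      layer,  sign, count, izh
    ("L2_pyramidal",             "L2/3", +1, 550, _RS),
    ("L3_pyramidal",             "L2/3", +1, 1150, _RS),
    ("L23_PV_FS",                "L2/3", -1, 60, _FS),
    ("L23_PV_bursting",          "L2/3", -1, 25, _BURST),
    ("L23_SST_martinotti",       "L2/3", -1, 55, _LTS),
    ("L23_neurogliaform",        "L2/3", -1, 30, _LTS),
    ("L23_CR_bipolar",           "L2/3", -1, 20, _LTS),
    ("L23_CR_VIP_multipolar",    "L2/3", -1, 20, _LTS),
    ("L23_VIP_CRneg",            "L2/3", -1, 25, _LTS),
    ("L4_spiny_stellate",        "L4",   +1, 1200, _RS),
    ("L4_star_pyramidal",        "L4",   +1, 250, _RS),
    ("L4_PV_FS",                 "L4",   -1, 100, _FS),
    ("L4_PVneg_LTS",             "L4",   -1, 50, _LTS),
]


def adaptive_threshold_params(type_name: str) -> AdaptiveThresholdParams:
    """Stand-in adaptive-threshold constants (shared across types)."""
    return AdaptiveThresholdParams()


def default_registry(scale: float = 1.0) -> list[CellTypeSpec]:
    """The 13-type registry; counts scaled by ``scale`` (min 1 per type)."""
    registry = []
    for name, layer, sign, count, izh in _TYPE_TABLE:
        n = max(int(round(count * scale)), 1) if count > 0 else 0
        registry.append(
            CellTypeSpec(
                name=name,
                layer=layer,
                sign=sign,
                count=n,
                izh_mean=izh,
                izh_sd=_sd(izh),
                threshold_params=vars(adaptive_threshold_params(name)),
            )
        )
    return registry


def default_geometry(n_columns: int = 1) -> ColumnGeometry:
    return ColumnGeometry(n_columns=n_columns)


# --------------------------------------------------------------------------
# coarse cell groups used to key pathway tables

CELL_GROUPS = {
    "L2_pyramidal": "L23e",
    "L3_pyramidal": "L23e",
    "L23_PV_FS": "L23i",
    "L23_PV_bursting": "L23i",
    "L23_SST_martinotti": "L23i",
    "L23_neurogliaform": "L23i",
    "L23_CR_bipolar": "L23i",
    "L23_CR_VIP_multipolar": "L23i",
    "L23_VIP_CRneg": "L23i",
    "L4_spiny_stellate": "L4e",
    "L4_star_pyramidal": "L4e",
    "L4_PV_FS": "L4i",
    "L4_PVneg_LTS": "L4i",
    "VPM": "VPM",
}


def group_of(type_name: str) -> str:
    return CELL_GROUPS[type_name]


# --------------------------------------------------------------------------
# projection fields (axonal / dendritic 3-D Gaussians, µm)
# z offsets are in depth coordinates (positive = deeper)

_AXON_FIELDS = {
    "L23e": ProjectionField("axonal", offset=(0, 0, 0), sigmas=(180.0, 180.0, 120.0)),
    "L23i": ProjectionField("axonal", offset=(0, 0, 0), sigmas=(90.0, 90.0, 90.0)),
    # L4 excitatory axons arborize locally and project up into L2/3
    "L4e": ProjectionField("axonal", offset=(0, 0, -80.0), sigmas=(110.0, 110.0, 160.0)),
    "L4i": ProjectionField("axonal", offset=(0, 0, 0), sigmas=(80.0, 80.0, 80.0)),
}

_DENDRITE_FIELDS = {
    # pyramidal dendrites: soma-centered basal + apical skew upward
    "L23e": ProjectionField("dendritic", offset=(0, 0, -40.0), sigmas=(80.0, 80.0, 110.0)),
    "L23i": ProjectionField("dendritic", offset=(0, 0, 0), sigmas=(60.0, 60.0, 60.0)),
    "L4e": ProjectionField("dendritic", offset=(0, 0, -20.0), sigmas=(70.0, 70.0, 90.0)),
    "L4i": ProjectionField("dendritic", offset=(0, 0, 0), sigmas=(60.0, 60.0, 60.0)),
}

#: VPM afferent axons ramify in a barrel-shaped cloud centered on L4 with a
#: tail reaching the bottom of L2/3; the offset lifts the field from the
#: (virtual) thalamic soma position up into the column.
THALAMIC_SOMA_DEPTH = 900.0


def vpm_axon_field() -> ProjectionField:
    return ProjectionField("axonal", offset=(0, 0, -(THALAMIC_SOMA_DEPTH - 535.0)),
                           sigmas=(80.0, 80.0, 90.0))


def thalamic_dendrite_field() -> ProjectionField:
    # only used as a formal target when wiring *to* thalamus (not modeled)
    return ProjectionField("dendritic", sigmas=(50.0, 50.0, 50.0))


def projection_fields(type_name: str) -> tuple[ProjectionField, ProjectionField]:
    """(axonal, dendritic) fields of a cortical type or VPM."""
    if type_name == "VPM":
        return vpm_axon_field(), thalamic_dendrite_field()
    g = group_of(type_name)
    return _AXON_FIELDS[g], _DENDRITE_FIELDS[g]


# --------------------------------------------------------------------------
# pairwise connection probabilities within 100 µm (stand-ins, group level)

_CONNECTION_P = {
    ("VPM", "L4e"): 0.40,
    ("VPM", "L4i"): 0.50,
    ("VPM", "L23e"): 0.05,
    ("VPM", "L23i"): 0.05,
    ("L4e", "L4e"): 0.20,
    ("L4e", "L4i"): 0.40,
    ("L4i", "L4e"): 0.50,
    ("L4i", "L4i"): 0.50,
    ("L4e", "L23e"): 0.15,
    ("L4e", "L23i"): 0.20,
    ("L23e", "L23e"): 0.15,
    ("L23e", "L23i"): 0.40,
    ("L23i", "L23e"): 0.50,
    ("L23i", "L23i"): 0.40,
    ("L23e", "L4e"): 0.05,
    ("L23e", "L4i"): 0.05,
}


def connection_probability(pre_type: str, post_type: str) -> float:
    """Target pairwise connection probability within 100 µm (0 if absent)."""
    return _CONNECTION_P.get((group_of(pre_type), group_of(post_type)), 0.0)


# --------------------------------------------------------------------------
# synapse statistics per pathway group (stand-ins)
# amp: effective PSP peak (mV, at rest); rise: 10-90% (ms); hw: half-width
# (ms); failure: per-spike failure probability; cv: amplitude CV;
# p: short-term plasticity jump factor; tau_x: recovery (ms)
#
# Amplitudes are calibrated so the default column sits at the reported
# operating point (sparse excitatory firing, reliable but bounded
# inhibitory firing, state-dependent gating of L2/3): thalamocortical
# drive is strong and fast, feedforward inhibition onto interneurons is
# comparatively weak because interneurons already receive massive
# convergent excitation, and inhibitory amplitudes are large to keep the
# evoked response transient.

_SYNAPSE_TABLE = {
    ("VPM", "L4e"): dict(amp=0.45, rise=0.6, hw=4.0, failure=0.1, cv=0.25, p=0.6, tau_x=150.0),
    ("VPM", "L4i"): dict(amp=0.63, rise=0.4, hw=3.0, failure=0.05, cv=0.25, p=0.6, tau_x=150.0),
    ("VPM", "L23e"): dict(amp=0.36, rise=0.6, hw=4.0, failure=0.1, cv=0.25, p=0.6, tau_x=150.0),
    ("VPM", "L23i"): dict(amp=0.36, rise=0.4, hw=3.0, failure=0.1, cv=0.25, p=0.6, tau_x=150.0),
    ("L4e", "L4e"): dict(amp=0.45, rise=0.8, hw=10.0, failure=0.3, cv=0.3, p=0.7, tau_x=150.0),
    ("L4e", "L4i"): dict(amp=0.20, rise=0.5, hw=6.0, failure=0.15, cv=0.3, p=0.8, tau_x=150.0),
    ("L4i", "L4e"): dict(amp=1.19, rise=0.8, hw=12.0, failure=0.1, cv=0.3, p=0.9, tau_x=150.0),
    ("L4i", "L4i"): dict(amp=0.99, rise=0.8, hw=10.0, failure=0.1, cv=0.3, p=0.9, tau_x=150.0),
    ("L4e", "L23e"): dict(amp=0.63, rise=0.8, hw=10.0, failure=0.3, cv=0.3, p=0.7, tau_x=150.0),
    ("L4e", "L23i"): dict(amp=0.27, rise=0.5, hw=6.0, failure=0.15, cv=0.3, p=0.8, tau_x=150.0),
    ("L23e", "L23e"): dict(amp=0.23, rise=0.8, hw=10.0, failure=0.3, cv=0.3, p=0.7, tau_x=150.0),
    ("L23e", "L23i"): dict(amp=0.11, rise=0.5, hw=6.0, failure=0.15, cv=0.3, p=0.8, tau_x=150.0),
    ("L23i", "L23e"): dict(amp=1.09, rise=0.8, hw=12.0, failure=0.1, cv=0.3, p=0.9, tau_x=150.0),
    ("L23i", "L23i"): dict(amp=0.79, rise=0.8, hw=10.0, failure=0.1, cv=0.3, p=0.9, tau_x=150.0),
    ("L23e", "L4e"): dict(amp=0.18, rise=0.8, hw=10.0, failure=0.3, cv=0.3, p=0.7, tau_x=150.0),
    ("L23e", "L4i"): dict(amp=0.07, rise=0.5, hw=6.0, failure=0.15, cv=0.3, p=0.8, tau_x=150.0),
}


def synapse_params(pre_type: str, post_type: str) -> dict | None:
    """Synapse statistics for a pathway, or None when the pathway is absent."""
    key = (group_of(pre_type), group_of(post_type))
    params = _SYNAPSE_TABLE.get(key)
    return dict(params) if params is not None else None


#: thalamic barreloid size for a full-scale column (paper range 100-200;
#: 200 used for the in-vivo-like filter-and-fire experiment)
N_PER_BARRELOID = 200
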