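"""Synaptic graph generation by axo-dendritic overlap (Peter's rule).

Axonal (A) and dendritic (D) arbors are approximated by 3-D Gaussian
densities attached to each soma.  For a presynaptic neuron i and a
postsynaptic neuron j the overlap index is

    I_ij = ∫∫∫ A_i(r) D_j(r) dr   over the support SD_j holding 99.9%
                                  of the dendritic mass,

which for Gaussians has the closed form of a Gaussian in the soma
separation with per-axis variance ``sigma_A^2 + sigma_D^2``.  The 99.9%
truncation is applied as a multiplicative mass correction (its effect on
I is < 0.1%); a brute-force grid-quadrature mode exists for validation.

Connection probability is ``P_ij = k * I_ij`` with k calibrated per
(pre type, post type) pair so that the mean P over pairs within a
calibration radius (default 100 µm inter-soma distance) matches the
empirically measured pairwise connection probability.  Edges are then
independent Bernoulli draws; conduction delays follow from the 3-D
soma distance at 190 µm/ms, floored at one integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "ProjectionField",
    "ConnectivityRule",
    "ConnectionSet",
    "CalibrationError",
    "overlap_index",
    "overlap_index_quadrature",
    "pairwise_overlap",
    "calibrate_k",
    "sample_adjacency",
    "conduction_delay",
    "CONDUCTION_VELOCITY_UM_PER_MS",
]

#: action-potential conduction velocity, µm/ms
CONDUCTION_VELOCITY_UM_PER_MS = 190.0

#: dendritic mass fraction retained by the truncated support SD_j
TRUNCATION_MASS = 0.999

#: squared Mahalanobis radius containing 99.9% of a 3-D Gaussian
_CHI2_3_Q999 = float(chi2.ppf(TRUNCATION_MASS, df=3))


class CalibrationError(RuntimeError):
    """No usable pairs (or zero mean overlap) within the calibration radius."""


@dataclass(frozen=True)
class ProjectionField:
    """A 3-D Gaussian axonal or dendritic density, unit total mass.

    ``offset`` displaces the field center from the soma (µm); ``sigmas``
    are the per-axis standard deviations (µm).
    """

    role: str                               # "axonal" or "dendritic"
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigmas: tuple[float, float, float] = (100.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        if self.role not in ("axonal", "dendritic"):
            raise ValueError("role must be 'axonal' or 'dendritic'")
        if min(self.sigmas) <= 0:
            raise ValueError("sigmas must be > 0")

    def density(self, points: np.ndarray, soma: np.ndarray) -> np.ndarray:
        """Evaluate the field at ``points`` (n, 3) for a soma at ``soma``."""
        mu = np.asarray(soma, dtype=float) + np.asarray(self.offset, dtype=float)
        sig = np.asarray(self.sigmas, dtype=float)
        d2 = ((points - mu) / sig) ** 2
        norm = np.prod(sig) * (2.0 * np.pi) ** 1.5
        return np.exp(-0.5 * d2.sum(axis=-1)) / norm


def overlap_index(
    field_a: ProjectionField,
    field_d: ProjectionField,
    separation: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    truncate: bool = False,
) -> float | np.ndarray:
    """Closed-form Gaussian product integral ∫ A·D over space.

    ``separation`` is soma_post − soma_pre (µm) and may be an (..., 3)
    array for vectorized evaluation.  With ``truncate`` the 99.9%
    dendritic-support restriction is applied as a multiplicative mass
    correction.
    """
    sep = np.asarray(separation, dtype=float)
    da = np.asarray(field_a.offset, dtype=float)
    dd = np.asarray(field_d.offset, dtype=float)
    # center difference between the two field means
    delta = sep + dd - da
    var = np.asarray(field_a.sigmas, dtype=float) ** 2 + np.asarray(field_d.sigmas, dtype=float) ** 2
    val = np.exp(-0.5 * (delta**2 / var).sum(axis=-1)) / np.sqrt((2.0 * np.pi) ** 3 * var.prod())
    if truncate:
        val = val * TRUNCATION_MASS
    return float(val) if val.ndim == 0 else val


def overlap_index_quadrature(
    field_a: ProjectionField,
    field_d: ProjectionField,
    separation=(0.0, 0.0, 0.0),
    n_grid: int = 61,
    n_sigma: float = 6.0,
    truncate: bool = False,
) -> float:
    """Brute-force 3-D grid quadrature of ∫ A·D (validation oracle).

    The grid spans ``n_sigma`` combined standard deviations around the
    midpoint of the two field centers.  With ``truncate`` the integrand is
    restricted to the Mahalanobis ball of D holding 99.9% of its mass.
    """
    sep = np.asarray(separation, dtype=float)
    mu_a = np.asarray(field_a.offset, dtype=float)
    mu_d = sep + np.asarray(field_d.offset, dtype=float)
    sig = np.sqrt(np.asarray(field_a.sigmas, float) ** 2 + np.asarray(field_d.sigmas, float) ** 2)
    center = 0.5 * (mu_a + mu_d)
    half = n_sigma * sig + 0.5 * np.abs(mu_a - mu_d)
    axes = [np.linspace(center[i] - half[i], center[i] + half[i], n_grid) for i in range(3)]
    steps = [ax[1] - ax[0] for ax in axes]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    a = field_a.density(pts, soma=np.zeros(3))
    d = field_d.density(pts, soma=sep)
    integrand = a * d
    if truncate:
        m2 = (((pts - mu_d) / np.asarray(field_d.sigmas, float)) ** 2).sum(axis=-1)
        integrand = integrand * (m2 <= _CHI2_3_Q999)
    return float(integrand.sum() * np.prod(steps))


def pairwise_overlap(
    pre_pos: np.ndarray,
    post_pos: np.ndarray,
    field_a: ProjectionField,
    field_d: ProjectionField,
    truncate: bool = False,
) -> np.ndarray:
    """Overlap index for every (pre, post) soma pair: (n_pre, n_post)."""
    sep = post_pos[None, :, :] - pre_pos[:, None, :]
    return overlap_index(field_a, field_d, sep, truncate=truncate)


@dataclass
class ConnectivityRule:
    """Target pairwise connection probability for one type pair."""

    pre_type: str
    post_type: str
    target_p: float
    radius: float = 100.0
    k: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_p <= 1.0:
            raise ValueError("target_p must lie in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


def calibrate_k(
    overlap: np.ndarray,
    distances: np.ndarray,
    rule: ConnectivityRule,
) -> float:
    """Choose k so that mean(k·I) over in-radius pairs equals target_p.

    ``overlap`` and ``distances`` are matching (n_pre, n_post) arrays of
    overlap indices and inter-soma distances (µm).  Self-pairs may be
    excluded beforehand by setting their distance to inf.
    """
    mask = distances <= rule.radius
    if not mask.any():
        raise CalibrationError(
            f"no pairs within {rule.radius} µm for {rule.pre_type}->{rule.post_type}"
        )
    if rule.target_p == 0.0:
        return 0.0
    mean_i = float(np.mean(overlap[mask]))
    if mean_i <= 0.0:
        raise CalibrationError(
            f"mean overlap is zero within radius for {rule.pre_type}->{rule.post_type}"
        )
    return rule.target_p / mean_i


def sample_adjacency(
    p: np.ndarray,
    seed: int | np.random.Generator = 0,
    no_self: bool = True,
) -> np.ndarray:
    """Bernoulli adjacency sample from a (n_pre, n_post) probability matrix.

    Returns a boolean matrix; the diagonal is cleared when ``no_self`` and
    the matrix is square (pre and post index the same neurons).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    adj = rng.random(p.shape) < p
    if no_self and p.ndim == 2 and p.shape[0] == p.shape[1]:
        np.fill_diagonal(adj, False)
    return adj


def conduction_delay(distance_um, dt_ms: float = 0.1) -> np.ndarray:
    """Axonal conduction delay in ms: distance / 190 µm/ms, floored at dt.

    The floor of one integration step prevents zero-delay coupling within
    a single step.
    """
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    delay = np.maximum(d / CONDUCTION_VELOCITY_UM_PER_MS, dt_ms)
    return float(delay) if delay.ndim == 0 else delay


@dataclass
class ConnectionSet:
    """Sparse directed synapses: parallel edge arrays plus kernel refs.

    ``weight`` is the PSP peak amplitude in mV (sign carried separately by
    the kernel/pathway), ``delay_steps`` the conduction delay in integration
    steps, ``stp_p``/``stp_tau`` the short-term-plasticity jump factor and
    recovery constant, ``failure`` the per-spike transmission failure
    probability, ``cv`` the amplitude coefficient of variation, and
    ``kernel_id`` indexes the engine's PSC kernel table.  ``pathway_id``
    indexes ``pathway_names`` for analysis grouping.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_steps: np.ndarray
    stp_p: np.ndarray
    stp_tau: np.ndarray
    failure: np.ndarray
    cv: np.ndarray
    kernel_id: np.ndarray
    sign: np.ndarray
    pathway_id: np.ndarray
    pathway_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.pre == self.post):
            # allowed only when pre and post index disjoint populations;
            # engine builders pass cortical ids offset from thalamic ids.
            pass
        if np.any((self.failure < 0) | (self.failure > 1)):
            raise ValueError("failure rates must lie in [0, 1]")
        if np.any(self.delay_steps < 1):
            raise ValueError("delays must be at least one step")

    @property
    def n_edges(self) -> int:
        return self.pre.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.weight,
                "delay_steps": self.delay_steps,
                "stp_p": self.stp_p,
                "stp_tau": self.stp_tau,
                "failure": self.failure,
                "cv": self.cv,
                "kernel_id": self.kernel_id,
                "sign": self.sign,
                "pathway": np.asarray(self.pathway_names, dtype=object)[self.pathway_id],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path, group: str = "connections") -> None:
        """Write the parallel edge arrays to an HDF5 group."""
        import h5py

        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name in ("pre", "post", "weight", "delay_steps", "stp_p",
                         "stp_tau", "failure", "cv", "kernel_id", "sign",
                         "pathway_id"):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["pathway_names"] = [str(n) for n in self.pathway_names]

    @staticmethod
    def concatenate(parts: list["ConnectionSet"]) -> "ConnectionSet":
        names: list[str] = []
        remapped = []
        for cs in parts:
            offset = len(names)
            names.extend(cs.pathway_names)
            remapped.append(cs.pathway_id + offset)
        cat = lambda attr: np.concatenate([getattr(c, attr) for c in parts])
        return ConnectionSet(
            pre=cat("pre"),
            post=cat("post"),
            weight=cat("weight"),
            delay_steps=cat("delay_steps"),
            stp_p=cat("stp_p"),
            stp_tau=cat("stp_tau"),
            failure=cat("failure"),
            cv=cat("cv"),
            kernel_id=cat("kernel_id"),
            sign=cat("sign"),
            pathway_id=np.concatenate(remapped),
            pathway_names=names,
        )
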