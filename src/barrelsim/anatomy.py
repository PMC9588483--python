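"""Cell types, laminar density profiles and neuron placement.

The modeled slab is the top 630-640 µm of a barrel column: L2/3 (430 µm)
above L4 (210 µm), each 300 x 300 µm in the tangential plane.  The
coordinate convention is: z is depth from the pia-side top of the slab,
in µm, increasing downward; the origin sits at a column corner.  Layer
borders are obtained from NeuN+ density profiles by fitting a Gaussian
``g(z) = c1 + c2 * exp(-(z - z0)^2 / (2 sigma^2))`` and taking the
half-maximum depths ``z_lim = z0 +/- sigma * sqrt(2 ln 2)``.

Thirteen cortical cell types are modeled: 9 in L2/3 (2 excitatory, 7
inhibitory classes) and 4 in L4 (2 excitatory, 2 inhibitory).  Per-neuron
Izhikevich parameters (a, b, c, d) are drawn from per-type distributions
so that nominally identical neurons remain heterogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CellTypeSpec",
    "ColumnGeometry",
    "LayerProfileFit",
    "NeuronPopulation",
    "LayerFitError",
    "DegenerateProfileError",
    "fit_layer_profile",
    "compute_layer_borders",
    "sample_population",
]

#: half-width factor of a Gaussian: distance from center to half maximum.
HALF_MAX_FACTOR = math.sqrt(2.0 * math.log(2.0))


class LayerFitError(RuntimeError):
    """Layer-profile fit failed to converge or produced sigma <= 0."""


class DegenerateProfileError(LayerFitError):
    """Density profile is flat: the Gaussian bump is indistinguishable from 0."""


@dataclass(frozen=True)
class CellTypeSpec:
    """One of the 13 modeled cortical cell classes.

    ``izh_mean``/``izh_sd`` hold the (a, b, c, d) distribution of the
    Izhikevich dynamics; ``threshold_params`` holds the adaptive-threshold
    constants (tau_theta, alpha, v_i, v_T, k_alpha, k_i).
    """

    name: str
    layer: str               # "L2/3" or "L4"
    sign: int                # +1 excitatory, -1 inhibitory
    count: int
    izh_mean: tuple[float, float, float, float]
    izh_sd: tuple[float, float, float, float]
    threshold_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0 for {self.name}")
        if self.layer not in ("L2/3", "L4"):
            raise ValueError(f"unknown layer {self.layer!r} for {self.name}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1 for {self.name}")

    def with_count(self, count: int) -> "CellTypeSpec":
        return replace(self, count=int(count))


@dataclass(frozen=True)
class ColumnGeometry:
    """Spatial extent of the modeled column slab(s), in µm.

    z runs from 0 (top of L2/3) to ``l23_depth + l4_depth`` (bottom of L4).
    Multiple columns are laid out along x at ``inter_column_offset`` spacing.
    """

    x_extent: float = 300.0
    y_extent: float = 300.0
    l23_depth: float = 430.0
    l4_depth: float = 210.0
    n_columns: int = 1
    inter_column_offset: float = 300.0

    def __post_init__(self) -> None:
        if min(self.x_extent, self.y_extent, self.l23_depth, self.l4_depth) <= 0:
            raise ValueError("all extents must be > 0")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")

    @property
    def total_depth(self) -> float:
        return self.l23_depth + self.l4_depth

    def layer_slab(self, layer: str) -> tuple[float, float]:
        """(z_top, z_bottom) of a layer in depth coordinates."""
        if layer == "L2/3":
            return 0.0, self.l23_depth
        if layer == "L4":
            return self.l23_depth, self.l23_depth + self.l4_depth
        raise ValueError(f"unknown layer {layer!r}")

    def column_origin(self, column: int) -> float:
        return column * self.inter_column_offset


@dataclass(frozen=True)
class LayerProfileFit:
    """Result of the Gaussian fit to a cell-density depth profile."""

    c1: float
    c2: float
    z0: float
    sigma: float

    @property
    def z_lim(self) -> tuple[float, float]:
        return compute_layer_borders(self.z0, self.sigma)

    def density(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.c1 + self.c2 * np.exp(-((z - self.z0) ** 2) / (2.0 * self.sigma**2))


def _gauss(z, c1, c2, z0, sigma):
    return c1 + c2 * np.exp(-((z - z0) ** 2) / (2.0 * sigma**2))


def fit_layer_profile(density_vs_depth, rel_flat_tol: float = 1e-3) -> LayerProfileFit:
    """Least-squares Gaussian fit to a (depth µm, cells/mm^3) profile.

    Initial values are data-driven: ``c1`` from the minimum density, ``c2``
    from the min-to-max range and ``z0`` from the argmax depth.  A profile
    whose bump amplitude is indistinguishable from zero (relative to the
    offset) raises :class:`DegenerateProfileError`.
    """
    arr = np.asarray(density_vs_depth, dtype=float)
    if isinstance(density_vs_depth, pd.DataFrame):
        arr = density_vs_depth.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a table of (z_um, density_per_mm3)")
    if arr.shape[0] < 5:
        raise ValueError("need at least 5 depth bins")
    z, dens = arr[:, 0], arr[:, 1]
    if np.any(dens < 0):
        raise ValueError("densities must be >= 0")

    span = dens.max() - dens.min()
    scale = max(dens.max(), 1.0)
    if span <= rel_flat_tol * scale:
        raise DegenerateProfileError("flat density profile: c2 indistinguishable from 0")

    p0 = (dens.min(), span, z[np.argmax(dens)], 0.25 * (z.max() - z.min()) + 1e-9)
    try:
        popt, _ = curve_fit(_gauss, z, dens, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # non-convergence
        raise LayerFitError(f"Gaussian layer fit did not converge: {exc}") from exc
    c1, c2, z0, sigma = popt
    sigma = abs(sigma)  # the model is even in sigma
    if sigma <= 0 or not np.isfinite([c1, c2, z0, sigma]).all():
        raise LayerFitError("Gaussian layer fit produced invalid parameters")
    if c2 <= rel_flat_tol * scale:
        raise DegenerateProfileError("fitted bump amplitude indistinguishable from 0")
    return LayerProfileFit(c1=float(c1), c2=float(c2), z0=float(z0), sigma=float(sigma))


def compute_layer_borders(z0: float, sigma: float) -> tuple[float, float]:
    """Half-maximum depths of the fitted density bump.

    Returns ``(z0 - sigma*sqrt(2 ln 2), z0 + sigma*sqrt(2 ln 2))``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    half = sigma * HALF_MAX_FACTOR
    return (z0 - half, z0 + half)


@dataclass
class NeuronPopulation:
    """Typed, positioned neurons with per-neuron dynamics parameters.

    Column-oriented storage: all fields are 1-D arrays of length
    ``n_neurons``.  ``type_index`` indexes into ``registry``.
    """

    registry: list[CellTypeSpec]
    geometry: ColumnGeometry
    type_index: np.ndarray        # int
    column: np.ndarray            # int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    v_r: np.ndarray               # mV, resting potential
    v_t: np.ndarray               # mV, quadratic threshold parameter

    @property
    def n_neurons(self) -> int:
        return self.type_index.size

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_neurons)

    @property
    def sign(self) -> np.ndarray:
        return np.array([t.sign for t in self.registry])[self.type_index]

    @property
    def layer(self) -> np.ndarray:
        return np.array([t.layer for t in self.registry])[self.type_index]

    @property
    def type_name(self) -> np.ndarray:
        return np.array([t.name for t in self.registry])[self.type_index]

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def select(self, layer: str | None = None, sign: int | None = None,
               column: int | None = None, type_name: str | None = None) -> np.ndarray:
        """Boolean mask over neurons matching all given criteria."""
        mask = np.ones(self.n_neurons, dtype=bool)
        if layer is not None:
            mask &= self.layer == layer
        if sign is not None:
            mask &= self.sign == sign
        if column is not None:
            mask &= self.column == column
        if type_name is not None:
            mask &= self.type_name == type_name
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": self.type_name,
                "layer": self.layer,
                "column": self.column,
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "d": self.d,
                "v_r": self.v_r,
                "v_t": self.v_t,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_population(
    geometry: ColumnGeometry,
    registry: list[CellTypeSpec],
    seed: int | np.random.Generator = 0,
    v_r: float = -70.0,
    v_t_mean: float = -40.0,
    v_t_sd: float = 1.0,
) -> NeuronPopulation:
    """Place neurons uniformly inside their layer slab and draw dynamics.

    Placement is uniform in 3-D within the (layer, column) slab; per-type
    counts are exact; (a, b, c, d) are drawn from per-type normal
    distributions (negative a is clipped to a small positive floor so the
    recovery dynamics stay stable).  ``v_r`` sets the membrane state and is
    shared across the population; ``v_t`` gets a small per-neuron jitter.
    """
    rng = np.random.default_rng(seed)
    type_index, column, xs, ys, zs = [], [], [], [], []
    abcd = []
    for col in range(geometry.n_columns):
        x0 = geometry.column_origin(col)
        for ti, spec in enumerate(registry):
            n = spec.count
            if n == 0:
                continue
            z_top, z_bot = geometry.layer_slab(spec.layer)
            if z_bot <= z_top or geometry.x_extent <= 0 or geometry.y_extent <= 0:
                raise ValueError(f"zero-volume slab for {spec.name} with count {n}")
            xs.append(x0 + rng.uniform(0.0, geometry.x_extent, n))
            ys.append(rng.uniform(0.0, geometry.y_extent, n))
            zs.append(rng.uniform(z_top, z_bot, n))
            type_index.append(np.full(n, ti, dtype=int))
            column.append(np.full(n, col, dtype=int))
            draws = rng.normal(spec.izh_mean, spec.izh_sd, size=(n, 4))
            draws[:, 0] = np.clip(draws[:, 0], 1e-3, None)   # a > 0
            draws[:, 1] = np.clip(draws[:, 1], 1e-3, None)   # b > 0
            abcd.append(draws)

    if not type_index:
        raise ValueError("registry has no neurons to place")
    type_index = np.concatenate(type_index)
    n_total = type_index.size
    abcd = np.concatenate(abcd, axis=0)
    return NeuronPopulation(
        registry=list(registry),
        geometry=geometry,
        type_index=type_index,
        column=np.concatenate(column),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        z=np.concatenate(zs),
        a=abcd[:, 0],
        b=abcd[:, 1],
        c=abcd[:, 2],
        d=abcd[:, 3],
        v_r=np.full(n_total, float(v_r)),
        v_t=rng.normal(v_t_mean, v_t_sd, n_total),
    )
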