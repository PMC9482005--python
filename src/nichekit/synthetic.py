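"""Synthetic climate layers and virtual-species occurrences with known truth.

The generator provides everything the downstream niche and range analyses
need without any external downloads:

* :func:`generate_climate_stack` builds smooth, spatially autocorrelated
  predictor layers on a lon/lat grid, with deliberately collinear subsets
  (to exercise collinearity pruning) and a guaranteed latitudinal-gradient
  "thermal" layer (so an interpretable temperature-like axis always exists).
* :func:`generate_virtual_occurrences` samples native and introduced
  occurrence records from a known 2-D Gaussian niche in environment space,
  truncated to per-range windows, and returns the analytic expansion and
  unfilling fractions of that construction as :class:`SyntheticTruth`.

Truth fractions are mass fractions of the niche distribution: the expansion
fraction is the share of the introduced niche mass falling outside the
native window, and the unfilling fraction the share of native mass outside
the introduced window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ClimateStack, GridGeometry
from .occurrences import OccurrenceTable

__all__ = [
    "Window",
    "VirtualSpeciesSpec",
    "SyntheticTruth",
    "generate_climate_stack",
    "generate_virtual_occurrences",
    "UnreachableNicheError",
]


class UnreachableNicheError(ValueError):
    """No raster cell realizes environment values inside the requested window."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned box in 2-D environment space; bounds may be +-inf."""

    xmin: float = -math.inf
    xmax: float = math.inf
    ymin: float = -math.inf
    ymax: float = math.inf

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("window must be non-empty (min < max on both axes)")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x, y = np.asarray(x), np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


@dataclass
class VirtualSpeciesSpec:
    """A 2-D Gaussian niche and the sampling windows for each range."""

    niche_center: np.ndarray          # (2,) environment units
    niche_cov: np.ndarray             # (2, 2) positive definite
    native_window: Window
    introduced_window: Window
    n_native: int
    n_introduced: int
    seed: int
    env_layers: tuple[int, int] = (0, 1)  # stack layers defining the environment axes

    def __post_init__(self) -> None:
        self.niche_center = np.asarray(self.niche_center, dtype=float).reshape(2)
        self.niche_cov = np.asarray(self.niche_cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.niche_cov, self.niche_cov.T):
            raise ValueError("niche covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.niche_cov) <= 0):
            raise ValueError("niche covariance must be positive definite")
        if self.n_native < 1 or self.n_introduced < 1:
            raise ValueError("sample counts must be >= 1")


@dataclass
class SyntheticTruth:
    """Analytic ground truth of the virtual-species construction."""

    expected_E_fraction: float  # introduced niche mass outside the native window
    expected_U_fraction: float  # native niche mass outside the introduced window
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.expected_E_fraction, self.expected_U_fraction):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError("truth fractions must lie in [0, 1]")


def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int, sigma: float) -> np.ndarray:
    """Standardized low-pass-filtered white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_climate_stack(seed: int, nrows: int, ncols: int, n_layers: int,
                           collinear_groups: list[list[int]] | None = None,
                           xll: float = 0.0, yll: float = -30.0,
                           cellsize: float = 0.25,
                           smoothness: float | None = None) -> ClimateStack:
    """Generate smooth synthetic climate layers on a lon/lat grid.

    Layers listed together in one ``collinear_groups`` entry share a common
    smooth base field plus a small independent perturbation, forcing pairwise
    Pearson |r| > 0.9; layers in different groups are built from independent
    fields (|r| < 0.5 in expectation). Layer 0 always carries a latitudinal
    gradient so a thermal-like axis is present. Deterministic given ``seed``.

    Each layer is rank-uniformized onto the fixed value range [-3, 3] (a
    strictly monotone, smoothness-preserving transform), so the environment
    values realized across cells are uniformly available. Virtual-species
    occurrence sampling is then proportional to the niche density alone, and
    the analytic truncated-Gaussian truth of
    :func:`generate_virtual_occurrences` is the exact sampling limit.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("grid too small: need nrows >= 8 and ncols >= 8")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    collinear_groups = collinear_groups or []
    flat = [i for g in collinear_groups for i in g]
    if len(set(flat)) != len(flat):
        raise ValueError("collinear groups must be disjoint")
    if flat and (min(flat) < 0 or max(flat) >= n_layers):
        raise ValueError("collinear group indices out of range")

    rng = np.random.default_rng(seed)
    sigma = smoothness if smoothness is not None else max(2.0, min(nrows, ncols) / 10.0)
    geom = GridGeometry(nrows, ncols, xll, yll, cellsize)

    group_of = {i: g for g, members in enumerate(collinear_groups) for i in members}
    lat_grad = np.repeat(geom.lat_centers[:, None], ncols, axis=1)
    lat_grad = (lat_grad - lat_grad.mean()) / lat_grad.std()

    base_cache: dict[int, np.ndarray] = {}
    layers = np.empty((n_layers, nrows, ncols))
    for i in range(n_layers):
        if i in group_of:
            g = group_of[i]
            if g not in base_cache:
                base = _smooth_field(rng, nrows, ncols, sigma)
                if 0 in collinear_groups[g]:
                    base = (base + lat_grad) / math.sqrt(2.0)
                base_cache[g] = base
            # small smooth perturbation keeps within-group |r| ~ 0.99
            layers[i] = base_cache[g] + 0.15 * _smooth_field(rng, nrows, ncols, sigma)
        else:
            f = _smooth_field(rng, nrows, ncols, sigma)
            if i == 0:
                f = (f + lat_grad) / math.sqrt(2.0)
            layers[i] = f
        layers[i] = _rank_uniformize(layers[i])
    names = [f"env{i:02d}" for i in range(n_layers)]
    return ClimateStack(geom, names, layers, meta={"seed": seed})


def _rank_uniformize(field: np.ndarray, lo: float = -3.0, hi: float = 3.0) -> np.ndarray:
    """Monotone map of a field onto [lo, hi] with uniform cell-value availability."""
    flat = field.ravel()
    ranks = np.empty(flat.size)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    u = (ranks + 0.5) / flat.size
    return (lo + u * (hi - lo)).reshape(field.shape)


def _gaussian_density(x: np.ndarray, y: np.ndarray, spec: VirtualSpeciesSpec) -> np.ndarray:
    d = np.stack([np.asarray(x) - spec.niche_center[0],
                  np.asarray(y) - spec.niche_center[1]], axis=-1)
    prec = np.linalg.inv(spec.niche_cov)
    m2 = np.einsum("...i,ij,...j->...", d, prec, d)
    return np.exp(-0.5 * m2)


def _truth_fractions(spec: VirtualSpeciesSpec, n_quad: int = 400) -> SyntheticTruth:
    """Mass fractions by fixed n_quad x n_quad midpoint quadrature.

    The quadrature domain is the niche center +- 8 marginal standard
    deviations, which carries all but a negligible tail of the Gaussian mass;
    infinite window bounds are clipped to it.
    """
    sd = np.sqrt(np.diag(spec.niche_cov))
    lo = spec.niche_center - 8 * sd
    hi = spec.niche_center + 8 * sd
    xs = np.linspace(lo[0], hi[0], n_quad + 1)
    ys = np.linspace(lo[1], hi[1], n_quad + 1)
    xc = 0.5 * (xs[:-1] + xs[1:])
    yc = 0.5 * (ys[:-1] + ys[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    dens = _gaussian_density(X, Y, spec)
    in_nat = spec.native_window.contains(X, Y)
    in_int = spec.introduced_window.contains(X, Y)
    m_nat = dens[in_nat].sum()
    m_int = dens[in_int].sum()
    m_both = dens[in_nat & in_int].sum()
    if m_nat <= 0 or m_int <= 0:
        raise UnreachableNicheError("a sampling window carries no niche mass")
    e_frac = float((m_int - m_both) / m_int)
    u_frac = float((m_nat - m_both) / m_nat)
    return SyntheticTruth(min(max(e_frac, 0.0), 1.0), min(max(u_frac, 0.0), 1.0))


def _sample_range(rng: np.random.Generator, spec: VirtualSpeciesSpec, stack: ClimateStack,
                  window: Window, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-based rejection sampling of n occurrence points.

    A candidate cell (valid, environment inside the window) is drawn uniformly
    and accepted with probability proportional to the Gaussian niche density
    at its environment value; accepted points are jittered uniformly within
    the cell so records remain distinct.
    """
    li, lj = spec.env_layers
    valid = stack.valid_mask
    e1 = stack.values[li]
    e2 = stack.values[lj]
    cand = valid & window.contains(e1, e2)
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        raise UnreachableNicheError("no raster cell realizes the requested niche window")
    dens = _gaussian_density(e1[rows, cols], e2[rows, cols], spec)
    dmax = dens.max()
    if dmax <= 0:
        raise UnreachableNicheError("niche density vanishes over the window")
    p = dens / dmax
    geom = stack.geometry
    out_lon = np.empty(n)
    out_lat = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        batch = max(4 * (n - got), 256)
        idx = rng.integers(0, rows.size, size=batch)
        acc = rng.random(batch) < p[idx]
        take = idx[acc][: n - got]
        k = take.size
        lon_c, lat_c = geom.cell_centers(rows[take], cols[take])
        out_lon[got:got + k] = lon_c + (rng.random(k) - 0.5) * geom.cellsize
        out_lat[got:got + k] = lat_c + (rng.random(k) - 0.5) * geom.cellsize
        got += k
        attempts += batch
        if attempts > 10_000_000:
            raise UnreachableNicheError("rejection sampling failed to converge")
    return out_lon, out_lat


def generate_virtual_occurrences(spec: VirtualSpeciesSpec,
                                 stack: ClimateStack) -> tuple[OccurrenceTable, SyntheticTruth]:
    """Sample native and introduced occurrences of a virtual species.

    Returns the combined occurrence table (labels set) and the analytic
    :class:`SyntheticTruth` of the construction. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lon_n, lat_n = _sample_range(rng, spec, stack, spec.native_window, spec.n_native)
    lon_i, lat_i = _sample_range(rng, spec, stack, spec.introduced_window, spec.n_introduced)
    table = OccurrenceTable.from_points(
        np.concatenate([lon_n, lon_i]),
        np.concatenate([lat_n, lat_i]),
        np.concatenate([np.repeat("native", spec.n_native),
                        np.repeat("introduced", spec.n_introduced)]),
    )
    truth = _truth_fractions(spec)
    return table, truth
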