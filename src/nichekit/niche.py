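"""Niche occupancy in PC space and the COUE dynamics between two ranges.

The occurrence cloud of each range is smoothed with an axis-aligned Gaussian
kernel density estimator on a regular grid over the 2-D PC space; the
occupied niche is the smallest highest-density cell set carrying a given
mass quantile (default 95%). Overlaying the native and introduced occupancy
masks partitions environmental space into expansion E (introduced only),
stability S (both) and unfilling U (native only), from which the niche area
ratio NAR = NA_i / NA_n and Sorensen similarity SI = 2S / (NA_n + NA_i)
follow. Niche conservatism is rejected when NAR > 1 and SI < 0.5 (strict).

Areas are in squared PC units; because both ranges are estimated on one
shared grid, the identities NA_i = E + S and NA_n = S + U hold exactly as
cell-count arithmetic.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Verdict",
    "NicheGrid",
    "CoueResult",
    "silverman_bandwidth",
    "shared_grid_edges",
    "estimate_density",
    "occupancy_mask",
    "coue_partition",
    "conservatism_test",
    "niche_area_ratio",
    "sorensen_similarity",
]


class Verdict(str, enum.Enum):
    conservatism_rejected = "conservatism_rejected"
    conservatism_not_rejected = "conservatism_not_rejected"


@dataclass
class NicheGrid:
    """KDE density and occupancy mask on a regular grid over PC space.

    ``density`` is probability mass per unit area: summed over cells and
    multiplied by ``cell_area`` it integrates to 1.
    """

    axis1_edges: np.ndarray   # (K1 + 1,)
    axis2_edges: np.ndarray   # (K2 + 1,)
    density: np.ndarray       # (K1, K2)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis1_edges = np.asarray(self.axis1_edges, dtype=float)
        self.axis2_edges = np.asarray(self.axis2_edges, dtype=float)
        if np.any(np.diff(self.axis1_edges) <= 0) or np.any(np.diff(self.axis2_edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.axis1_edges.size - 1, self.axis2_edges.size - 1):
            raise ValueError("density shape does not match edges")

    @property
    def cell_area(self) -> float:
        return float((self.axis1_edges[1] - self.axis1_edges[0])
                     * (self.axis2_edges[1] - self.axis2_edges[0]))

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.axis1_edges[:-1] + self.axis1_edges[1:]),
                0.5 * (self.axis2_edges[:-1] + self.axis2_edges[1:]))

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    @property
    def masked_area(self) -> float:
        if self.mask is None:
            raise ValueError("occupancy mask not set")
        return float(self.mask.sum()) * self.cell_area

    def same_grid(self, other: "NicheGrid") -> bool:
        return (self.axis1_edges.shape == other.axis1_edges.shape
                and self.axis2_edges.shape == other.axis2_edges.shape
                and np.allclose(self.axis1_edges, other.axis1_edges)
                and np.allclose(self.axis2_edges, other.axis2_edges))


@dataclass
class CoueResult:
    """Expansion / stability / unfilling partition and conservatism statistics."""

    expansion: float            # E, PC-units^2
    stability: float            # S
    unfilling: float            # U
    area_native: float          # NA_n = S + U
    area_introduced: float      # NA_i = E + S
    nar: float                  # NA_i / NA_n
    si: float                   # 2S / (NA_n + NA_i)
    centroid_native: tuple[float, float]
    centroid_introduced: tuple[float, float]
    verdict: Verdict

    def to_dict(self) -> dict:
        d = {k: (v.value if isinstance(v, Verdict) else v) for k, v in self.__dict__.items()}
        d["centroid_native"] = list(self.centroid_native)
        d["centroid_introduced"] = list(self.centroid_introduced)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Per-axis Silverman rule of thumb: h = 1.06 * sd * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance axis: bandwidth undefined")
    return 1.06 * sd * x.size ** (-0.2)


def shared_grid_edges(score_sets: list[np.ndarray], grid_resolution: int = 200,
                      pad_bandwidths: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Grid edges spanning the pooled score range, padded by bandwidths.

    The pad per axis is ``pad_bandwidths`` times the largest per-set Silverman
    bandwidth, so every kernel's effective support is covered for all sets.
    """
    pooled = np.vstack(score_sets)
    edges = []
    for ax in range(2):
        h = max(silverman_bandwidth(s[:, ax]) for s in score_sets)
        lo = pooled[:, ax].min() - pad_bandwidths * h
        hi = pooled[:, ax].max() + pad_bandwidths * h
        edges.append(np.linspace(lo, hi, grid_resolution + 1))
    return edges[0], edges[1]


def estimate_density(scores: np.ndarray, grid_resolution: int = 200,
                     bandwidth_rule: str = "silverman",
                     fixed_bandwidth: tuple[float, float] | None = None,
                     edges: tuple[np.ndarray, np.ndarray] | None = None) -> NicheGrid:
    """Axis-aligned Gaussian KDE of 2-D scores on a regular grid.

    With ``edges`` unset the grid spans the scores' own range padded by three
    bandwidths per axis; pass edges from :func:`shared_grid_edges` to put two
    ranges on one commensurable grid. The density is evaluated at cell
    centers and renormalized so the total mass over the grid is exactly 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    n = scores.shape[0]
    if n < 5:
        raise ValueError("need at least 5 records for density estimation")
    if grid_resolution < 20:
        raise ValueError("grid_resolution must be >= 20")
    if bandwidth_rule == "silverman":
        h = np.array([silverman_bandwidth(scores[:, 0]), silverman_bandwidth(scores[:, 1])])
    elif bandwidth_rule == "fixed":
        if fixed_bandwidth is None:
            raise ValueError("fixed bandwidth_rule requires fixed_bandwidth")
        h = np.asarray(fixed_bandwidth, dtype=float)
        if np.any(h <= 0):
            raise ValueError("bandwidths must be positive")
    else:
        raise ValueError(f"unknown bandwidth_rule {bandwidth_rule!r}")

    if edges is None:
        e1 = np.linspace(scores[:, 0].min() - 3 * h[0], scores[:, 0].max() + 3 * h[0],
                         grid_resolution + 1)
        e2 = np.linspace(scores[:, 1].min() - 3 * h[1], scores[:, 1].max() + 3 * h[1],
                         grid_resolution + 1)
    else:
        e1, e2 = edges

    c1 = 0.5 * (e1[:-1] + e1[1:])
    c2 = 0.5 * (e2[:-1] + e2[1:])
    # separable product kernels: density = Gx @ Gy^T / n
    gx = np.exp(-0.5 * ((c1[:, None] - scores[None, :, 0]) / h[0]) ** 2) \
        / (h[0] * np.sqrt(2 * np.pi))
    gy = np.exp(-0.5 * ((c2[:, None] - scores[None, :, 1]) / h[1]) ** 2) \
        / (h[1] * np.sqrt(2 * np.pi))
    density = (gx @ gy.T) / n
    grid = NicheGrid(e1, e2, density)
    density /= grid.total_mass
    return NicheGrid(e1, e2, density)


def occupancy_mask(grid: NicheGrid, mass_quantile: float = 0.95) -> NicheGrid:
    """Smallest highest-density cell set carrying ``mass_quantile`` of the mass.

    Cells are accumulated in descending density order (ties broken row-major)
    until the summed mass reaches the quantile of the grid's total mass.
    """
    if not (0 < mass_quantile <= 1):
        raise ValueError("mass_quantile must be in (0, 1]")
    flat = grid.density.ravel()
    order = np.argsort(-flat, kind="stable")  # stable: ties keep row-major order
    csum = np.cumsum(flat[order]) * grid.cell_area
    target = mass_quantile * grid.total_mass
    k = int(np.searchsorted(csum, target - 1e-15)) + 1
    if mass_quantile == 1.0:
        chosen = order[flat[order] > 0]
    else:
        chosen = order[:k]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    return replace(grid, mask=mask.reshape(grid.density.shape))


def _centroid(grid: NicheGrid) -> tuple[float, float]:
    c1, c2 = grid.centers
    w = grid.density * grid.mask
    tot = w.sum()
    if tot == 0:
        return (float("nan"), float("nan"))
    return (float((w.sum(axis=1) @ c1) / tot), float((w.sum(axis=0) @ c2) / tot))


def coue_partition(native: NicheGrid, introduced: NicheGrid) -> CoueResult:
    """Partition the two occupancy masks into expansion, stability, unfilling.

    Both grids must share axes (build them with :func:`shared_grid_edges`).
    """
    if native.mask is None or introduced.mask is None:
        raise ValueError("both grids need occupancy masks (call occupancy_mask first)")
    if not native.same_grid(introduced):
        raise ValueError("niche grids are not aligned; estimate both on one shared grid")
    a = native.cell_area
    nm, im = native.mask, introduced.mask
    S = float((nm & im).sum()) * a
    E = float((im & ~nm).sum()) * a
    U = float((nm & ~im).sum()) * a
    na_n = S + U
    na_i = E + S
    nar = niche_area_ratio(na_n, na_i)
    si = sorensen_similarity(S, na_n, na_i)
    return CoueResult(E, S, U, na_n, na_i, nar, si,
                      _centroid(native), _centroid(introduced),
                      conservatism_test(nar, si))


def conservatism_test(nar: float, si: float) -> Verdict:
    """Reject niche conservatism iff NAR > 1 and SI < 0.5 (strict inequalities)."""
    if nar <= 0:
        raise ValueError("NAR must be positive")
    if not (0 <= si <= 1):
        raise ValueError("SI must lie in [0, 1]")
    if nar > 1 and si < 0.5:
        return Verdict.conservatism_rejected
    return Verdict.conservatism_not_rejected


def niche_area_ratio(na_n: float, na_i: float) -> float:
    """Niche area ratio NAR = NA_i / NA_n (introduced over native)."""
    if na_n <= 0:
        raise ZeroDivisionError("native niche area must be positive for NAR")
    return na_i / na_n


def sorensen_similarity(s: float, na_n: float, na_i: float) -> float:
    """Sorensen similarity SI = 2S / (NA_n + NA_i)."""
    if na_n + na_i <= 0:
        raise ValueError("niche areas must sum to a positive value")
    if s > min(na_n, na_i) * (1 + 1e-12) + 1e-12:
        raise ValueError("stability S cannot exceed either niche area")
    return 2.0 * s / (na_n + na_i)
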