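"""Potential ranges on the sphere and Mapcurves spatial concordance.

A suitability map thresholded at the MSS cutoff yields a binary potential
range; its surface area is summed from exact spherical cell areas
(R = 6371 km) and its latitudinal/longitudinal spans are naive max - min of
masked cell centers (no antimeridian wrapping). Concordance between two
binary maps is the Mapcurves goodness of fit, per category
``GOF = sum_i C_i/(B_i + C_i) * C_i/(A_i + C_i)`` where C is the cell count
of the intersection and A, B the counts exclusive to each map (the exclusive
convention makes GOF = 1 for identical maps; an inclusive switch implements
the literal reading where A and B include the intersection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import EARTH_RADIUS_KM, GridGeometry
from .sdm import SuitabilityMap

__all__ = ["BinaryRange", "GofResult", "binarize", "range_area_km2", "range_span",
           "mapcurve_gof"]


@dataclass
class BinaryRange:
    """Grid-aligned potential-range mask with spherical-area and span summaries."""

    geometry: GridGeometry
    mask: np.ndarray                 # (nrows, ncols) bool
    mss_threshold_used: float
    area_km2: float = 0.0
    lat_span_deg: float = 0.0
    lon_span_deg: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError("mask shape does not match geometry")
        if not (0.0 <= self.mss_threshold_used <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class GofResult:
    """Mapcurves goodness of fit and its per-category terms."""

    gof: float
    per_category_terms: list[tuple[int, int, int, float]]  # (C, A, B, term)

    def __post_init__(self) -> None:
        if not np.isclose(self.gof, sum(t[3] for t in self.per_category_terms)):
            raise ValueError("gof must equal the sum of the per-category terms")
        for _, _, _, term in self.per_category_terms:
            if not (0.0 <= term <= 1.0 + 1e-12):
                raise ValueError("each GOF term must lie in [0, 1]")


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryRange:
    """Potential range: valid cells with suitability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.isfinite(smap.values) & (smap.values >= threshold)
    rng = BinaryRange(smap.geometry, mask, threshold)
    rng.area_km2 = range_area_km2(rng)
    if mask.any():
        rng.lat_span_deg, rng.lon_span_deg = range_span(rng)
    return rng


def range_area_km2(rng: BinaryRange) -> float:
    """Spherical surface area of the masked cells in km^2.

    Each cell contributes R^2 * dlam * (sin(phi_top) - sin(phi_bottom)).
    """
    per_row = rng.geometry.cell_areas_km2()
    counts = rng.mask.sum(axis=1)
    return float(counts @ per_row)


def range_span(rng: BinaryRange) -> tuple[float, float]:
    """(lat span, lon span) in degrees across masked cell centers.

    Longitudes are taken on [-180, 180] as-is; an antimeridian-crossing range
    therefore reports the naive max - min span.
    """
    if not rng.mask.any():
        raise ValueError("span undefined for an empty range")
    rows, cols = np.nonzero(rng.mask)
    lats = rng.geometry.lat_centers[rows]
    lons = rng.geometry.lon_centers[cols]
    return float(lats.max() - lats.min()), float(lons.max() - lons.min())


def mapcurve_gof(map_a: BinaryRange, map_b: BinaryRange,
                 inclusive: bool = False) -> GofResult:
    """Mapcurves goodness of fit between two binary ranges on one grid.

    For the single in-range category, C counts cells present in both masks
    and A and B count cells exclusive to ``map_a`` and ``map_b`` (with
    ``inclusive=True``, A and B additionally count the intersection). The
    complementary out-of-range comparison is a second call on inverted masks.
    GOF is 0 when the masks do not intersect.
    """
    if map_a.geometry != map_b.geometry:
        raise ValueError("ranges are not on the same grid")
    c = int((map_a.mask & map_b.mask).sum())
    a_only = int((map_a.mask & ~map_b.mask).sum())
    b_only = int((map_b.mask & ~map_a.mask).sum())
    if inclusive:
        a_cnt, b_cnt = a_only + c, b_only + c
    else:
        a_cnt, b_cnt = a_only, b_only
    if c == 0:
        term = 0.0
    else:
        term = (c / (b_cnt + c)) * (c / (a_cnt + c))
    return GofResult(term, [(c, a_cnt, b_cnt, term)])
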