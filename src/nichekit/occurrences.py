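"""Occurrence records: reading, deduplication, spatial rarefaction, range split.

An :class:`OccurrenceTable` holds point records (id, lon, lat, range_label)
with WGS84 decimal-degree coordinates. ``range_label`` is ``"native"`` or
``"introduced"``; it may be missing on input and assigned later by
:func:`split_by_region`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import EARTH_RADIUS_KM

__all__ = [
    "OccurrenceTable",
    "read_occurrences",
    "rarefy",
    "split_by_region",
    "haversine_km",
    "FormatError",
    "EmptyInputError",
]

logger = logging.getLogger(__name__)

RANGE_LABELS = ("native", "introduced")


class FormatError(ValueError):
    """The occurrence file could not be parsed."""


class EmptyInputError(ValueError):
    """No valid occurrence records remain after filtering."""


@dataclass
class OccurrenceTable:
    """Point records with unique ids and no duplicated (lon, lat, label) triples."""

    df: pd.DataFrame  # columns: id, lon, lat, range_label

    def __post_init__(self) -> None:
        required = {"id", "lon", "lat", "range_label"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.df["id"].duplicated().any():
            raise ValueError("record ids must be unique")
        lon, lat = self.df["lon"].to_numpy(float), self.df["lat"].to_numpy(float)
        if np.any((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside WGS84 bounds")
        labels = self.df["range_label"]
        bad = labels.dropna()[~labels.dropna().isin(RANGE_LABELS)]
        if len(bad):
            raise ValueError(f"unknown range labels: {sorted(bad.unique())}")
        if self.df.duplicated(subset=["lon", "lat", "range_label"]).any():
            raise ValueError("duplicate (lon, lat, range_label) records")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy(float)

    @property
    def range_labels(self) -> np.ndarray:
        return self.df["range_label"].to_numpy()

    def subset_label(self, label: str) -> "OccurrenceTable":
        return OccurrenceTable(self.df[self.df["range_label"] == label].reset_index(drop=True))

    @classmethod
    def from_points(cls, lon, lat, range_label, start_id: int = 0) -> "OccurrenceTable":
        lon = np.asarray(lon, dtype=float)
        n = lon.size
        if np.isscalar(range_label) or isinstance(range_label, str):
            range_label = np.repeat(range_label, n)
        df = pd.DataFrame({
            "id": np.arange(start_id, start_id + n),
            "lon": lon,
            "lat": np.asarray(lat, dtype=float),
            "range_label": np.asarray(range_label, dtype=object),
        })
        return cls(df)

    def write_csv(self, path: str | Path, species: str = "virtual") -> None:
        out = self.df.rename(columns={"range_label": "range"}).copy()
        out.insert(0, "species", species)
        out.to_csv(path, index=False)


def read_occurrences(path: str | Path, dialect: dict[str, str] | None = None) -> OccurrenceTable:
    """Read an occurrence CSV, dropping invalid coordinates and exact duplicates.

    ``dialect`` maps canonical column names (``lon``, ``lat``, ``range``) to
    the file's actual column names. Rows with unparsable or out-of-range
    coordinates are dropped with a logged count; exact duplicate
    (lon, lat, label) rows collapse to one record.
    """
    dialect = dialect or {}
    colmap = {"lon": dialect.get("lon", "lon"),
              "lat": dialect.get("lat", "lat"),
              "range": dialect.get("range", "range")}
    try:
        raw = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for key in ("lon", "lat"):
        if colmap[key] not in raw.columns:
            raise FormatError(f"column {colmap[key]!r} not found in {path}")
    df = pd.DataFrame({
        "lon": pd.to_numeric(raw[colmap["lon"]], errors="coerce"),
        "lat": pd.to_numeric(raw[colmap["lat"]], errors="coerce"),
    })
    if colmap["range"] in raw.columns:
        df["range_label"] = raw[colmap["range"]].astype(object)
    else:
        df["range_label"] = pd.NA

    n0 = len(df)
    ok = (df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
          & df["lon"].notna() & df["lat"].notna())
    df = df[ok]
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d coordinate-invalid rows from %s", dropped, path)
    n1 = len(df)
    df = df.drop_duplicates(subset=["lon", "lat", "range_label"]).reset_index(drop=True)
    if n1 - len(df):
        logger.info("collapsed %d duplicate records from %s", n1 - len(df), path)
    if df.empty:
        raise EmptyInputError(f"no valid occurrence records in {path}")
    df.insert(0, "id", np.arange(len(df)))
    return OccurrenceTable(df)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float), np.asarray(lat1, float),
                                              np.asarray(lon2, float), np.asarray(lat2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def rarefy(table: OccurrenceTable, radius_km: float,
           shuffle_seed: int | None = None) -> OccurrenceTable:
    """Greedy spatial thinning: keep a record iff it is > ``radius_km`` from
    every already-kept record of the same range label.

    Candidates are visited in ascending-id order (deterministic); pass
    ``shuffle_seed`` to randomize the visiting order for sensitivity checks.
    Each range label is thinned independently.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    df = table.df.sort_values("id").reset_index(drop=True)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    keep_ids: list = []
    for label, sub in df.groupby("range_label", dropna=False, sort=False):
        lon, lat = sub["lon"].to_numpy(float), sub["lat"].to_numpy(float)
        kept: list[int] = []
        for i in range(len(sub)):
            if not kept:
                kept.append(i)
                continue
            d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
            if np.all(d > radius_km):
                kept.append(i)
        keep_ids.extend(sub["id"].to_numpy()[kept])
    out = table.df[table.df["id"].isin(keep_ids)].reset_index(drop=True)
    return OccurrenceTable(out)


def split_by_region(table: OccurrenceTable,
                    native_polygon: BaseGeometry) -> tuple[OccurrenceTable, OccurrenceTable]:
    """Label records native iff inside or on the boundary of ``native_polygon``.

    Returns (native, introduced) tables; counts are conserved.
    """
    if native_polygon is None or native_polygon.is_empty or not native_polygon.is_valid:
        raise ValueError("native polygon must be a valid, non-empty geometry")
    inside = np.array([native_polygon.covers(Point(x, y))
                       for x, y in zip(table.lon, table.lat)])
    df = table.df.copy()
    df["range_label"] = np.where(inside, "native", "introduced").astype(object)
    native = OccurrenceTable(df[inside].reset_index(drop=True))
    introduced = OccurrenceTable(df[~inside].reset_index(drop=True))
    return native, introduced
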