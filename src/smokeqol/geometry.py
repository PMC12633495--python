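"""Smoke-day classification from plume/study-area polygon overlap.

A calendar day is a *smoke day* when satellite-detected smoke-plume polygons
overlap the study area by at least a threshold area (default 1 km², boundary
inclusive).  All area arithmetic is done in a Lambert azimuthal equal-area
projection centred on the study area, so intersection areas come out in km²
regardless of where on the globe the study area sits.

Geometries are plain shapely objects in geographic (lon, lat) coordinates;
plume sets are lists of :class:`PlumeRecord`.  GeoJSON readers/writers live in
:mod:`smokeqol.io`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius, spherical model

__all__ = [
    "EARTH_RADIUS_KM",
    "LambertAzimuthalEqualArea",
    "StudyArea",
    "PlumeRecord",
    "default_study_area",
    "overlap_area",
    "detect_smoke_days",
]


class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection, outputs in km.

    The projection is exactly area-preserving on the sphere, so polygon areas
    computed in the projected plane equal their spherical areas.  One instance
    is anchored at a (lon0, lat0) tangent point, normally the study-area
    centroid.
    """

    def __init__(self, lon0: float, lat0: float, radius_km: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.R = float(radius_km)

    def forward(self, coords: np.ndarray) -> np.ndarray:
        """(n, 2) lon/lat degrees -> (n, 2) x/y km."""
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        lon0 = np.radians(self.lon0)
        lat0 = np.radians(self.lat0)
        dlon = lon - lon0
        # k' blows up only at the antipode of the tangent point
        denom = 1.0 + np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
        if np.any(denom <= 1e-12):
            raise ValueError("point at or near the projection antipode")
        k = self.R * np.sqrt(2.0 / denom)
        x = k * np.cos(lat) * np.sin(dlon)
        y = k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
        return np.column_stack([x, y])

    def inverse(self, coords: np.ndarray) -> np.ndarray:
        """(n, 2) x/y km -> (n, 2) lon/lat degrees."""
        x = coords[:, 0] / self.R
        y = coords[:, 1] / self.R
        lat0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(
                rho < 1e-12,
                lat0,
                np.arcsin(np.clip(
                    np.cos(c) * np.sin(lat0) + y * np.sin(c) * np.cos(lat0) / np.where(rho == 0, 1, rho),
                    -1.0, 1.0,
                )),
            )
            lon = np.radians(self.lon0) + np.where(
                rho < 1e-12,
                0.0,
                np.arctan2(x * np.sin(c), rho * np.cos(c) * np.cos(lat0) - y * np.sin(c) * np.sin(lat0)),
            )
        return np.column_stack([np.degrees(lon), np.degrees(lat)])

    def project(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely.transform(geom, self.forward)

    def unproject(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely.transform(geom, self.inverse)


def _repair(geom: BaseGeometry, label: str) -> BaseGeometry:
    """Zero-buffer repair for sliver/self-intersection defects; hard error if unfixable."""
    if geom.is_valid:
        return geom
    fixed = geom.buffer(0)
    if not fixed.is_valid or fixed.is_empty:
        raise ValueError(f"unrepairable geometry: {label}")
    return fixed


@dataclass
class StudyArea:
    """Fixed analysis polygon, in geographic lon/lat coordinates."""

    geometry: BaseGeometry
    name: str = "study area"

    def __post_init__(self) -> None:
        self.geometry = _repair(self.geometry, self.name)
        self.projection = LambertAzimuthalEqualArea(*np.asarray(self.geometry.centroid.coords[0]))
        self._projected = self.projection.project(self.geometry)
        if self._projected.area <= 0:
            raise ValueError(f"study area {self.name!r} has zero area")

    @property
    def projected(self) -> BaseGeometry:
        """Study area in the anchored equal-area plane (km units)."""
        return self._projected

    @property
    def total_area(self) -> float:
        """Total area in km²."""
        return float(self._projected.area)


@dataclass
class PlumeRecord:
    """One smoke-plume polygon observed on one calendar day."""

    date: _dt.date
    geometry: BaseGeometry
    density: str | None = None  # HMS density class, carried through unused
    label: str = field(default="plume")

    def __post_init__(self) -> None:
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)
        if isinstance(self.date, _dt.datetime):
            self.date = self.date.date()
        self.geometry = _repair(self.geometry, f"{self.label} {self.date}")


# Default study area: a synthetic stand-in for the four-county greater
# Albuquerque catchment (Bernalillo, Sandoval, Valencia, Torrance), scaled so
# its equal-area total matches the catchment's 18,719 km².  The true county
# polygons are not redistributable here; only the total area and rough
# location/shape are emulated.
_ALBUQUERQUE = (-106.6, 34.9)
_DEFAULT_AREA_KM2 = 18_719.0
# irregular octagon (unit scale, planar km before scaling) — loosely elongated
# north-south like the real four-county block
_TEMPLATE = np.array([
    (0.55, 1.00), (1.00, 0.45), (0.80, -0.35), (0.45, -1.05),
    (-0.25, -1.10), (-0.95, -0.50), (-1.05, 0.30), (-0.35, 1.05),
])


def default_study_area(total_area_km2: float = _DEFAULT_AREA_KM2,
                       center: tuple[float, float] = _ALBUQUERQUE) -> StudyArea:
    """Synthetic four-county-style study area with the given total area (km²)."""
    template = Polygon(_TEMPLATE)
    scale = np.sqrt(total_area_km2 / template.area)
    proj = LambertAzimuthalEqualArea(*center)
    planar = Polygon(_TEMPLATE * scale)
    geom = proj.unproject(planar)
    return StudyArea(geometry=geom, name="synthetic four-county catchment")


def overlap_area(plumes_on_day: Iterable[PlumeRecord | BaseGeometry], area: StudyArea) -> float:
    """Area (km²) of (union of the day's plumes) ∩ study area.

    Plumes are unioned first so overlapping plumes within a day are not
    double-counted: the quantity is coverage, not a per-plume sum.
    """
    geoms = []
    for p in plumes_on_day:
        g = p.geometry if isinstance(p, PlumeRecord) else _repair(p, "plume")
        geoms.append(area.projection.project(g))
    if not geoms:
        return 0.0
    merged = unary_union(geoms)
    return float(merged.intersection(area.projected).area)


def detect_smoke_days(
    plumes: Sequence[PlumeRecord],
    area: StudyArea,
    start: _dt.date | str,
    end: _dt.date | str,
    threshold_km2: float = 1.0,
) -> pd.DataFrame:
    """Classify every day in [start, end] as smoke / non-smoke.

    Returns a DataFrame indexed by date with columns ``is_smoke`` (bool) and
    ``overlap_km2``; a day is a smoke day iff the unioned plume–study-area
    overlap is at least ``threshold_km2`` (boundary inclusive).  Days with no
    plume records are non-smoke with overlap 0.
    """
    if threshold_km2 <= 0:
        raise ValueError("threshold_km2 must be positive")
    start = _dt.date.fromisoformat(start) if isinstance(start, str) else start
    end = _dt.date.fromisoformat(end) if isinstance(end, str) else end
    if end < start:
        raise ValueError("empty date range: end precedes start")

    by_day: dict[_dt.date, list[PlumeRecord]] = {}
    for p in plumes:
        by_day.setdefault(p.date, []).append(p)

    dates = pd.date_range(start, end, freq="D").date
    areas = np.zeros(len(dates))
    for i, d in enumerate(dates):
        if d in by_day:
            areas[i] = overlap_area(by_day[d], area)
    table = pd.DataFrame(
        {"is_smoke": areas >= threshold_km2, "overlap_km2": areas},
        index=pd.DatetimeIndex(pd.to_datetime(dates), name="date"),
    )
    return table
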