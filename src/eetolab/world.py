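"""Synthetic study region: extent, port, bathymetry and closure polygon.

The default world is a Gulf-like continental shelf: a coastline along the
northern edge with a single port, depth increasing smoothly offshore
(southward) with two gentle ridges, a lattice of candidate fishing sites on
the shelf, and a rectangular "core" of preferentially used sites that is
abruptly closed at the disturbance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely import contains_xy as shapely_contains_xy
from shapely.geometry import Polygon, box, mapping, shape

from eetolab.errors import ConfigurationError


@dataclass
class SimWorld:
    """Spatial context for the simulation and for depth attachment.

    ``depth_fn(lon, lat)`` must be deterministic, vectorized and return
    metres below sea level (>= 0 inside the extent).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    port: tuple
    closure: Polygon
    depth_fn: Callable = field(repr=False)
    #: lattice of candidate fishing sites (lon, lat) and their sampling weights
    site_lon: np.ndarray = field(repr=False, default=None)
    site_lat: np.ndarray = field(repr=False, default=None)
    site_weight: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ConfigurationError("world extent must have positive width and height")
        ext = box(self.lon_min, self.lat_min, self.lon_max, self.lat_max)
        if not ext.contains(self.closure):
            raise ConfigurationError("closure polygon must lie within the world extent")
        # spot-check non-negative depth on a coarse grid
        lo = np.linspace(self.lon_min, self.lon_max, 12)
        la = np.linspace(self.lat_min, self.lat_max, 12)
        gx, gy = np.meshgrid(lo, la)
        d = np.asarray(self.depth_fn(gx, gy))
        if np.any(d < 0):
            raise ConfigurationError("depth_fn must be >= 0 everywhere in the extent")

    @property
    def extent(self) -> tuple:
        return (self.lon_min, self.lon_max, self.lat_min, self.lat_max)

    def depth(self, lon, lat):
        return self.depth_fn(np.asarray(lon, float), np.asarray(lat, float))

    def closure_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "closure"},
                    "geometry": mapping(self.closure),
                }
            ],
        }

    @staticmethod
    def closure_from_geojson(doc: dict) -> Polygon:
        feats = doc.get("features", [])
        if not feats:
            raise ConfigurationError("GeoJSON document contains no features")
        geom = shape(feats[0]["geometry"])
        if not isinstance(geom, Polygon):
            raise ConfigurationError("closure geometry must be a single polygon")
        return geom


def _default_depth(lon, lat):
    """Linear offshore (southward) gradient plus two smooth ridges, metres."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    x = (lon + 88.0) / 5.0  # 0..1 across the extent
    y = (28.5 - lat) / 4.5  # 0 at coast, 1 fully offshore
    base = 12.0 + 450.0 * y
    ridges = 35.0 * np.sin(3.0 * np.pi * x) * np.sin(2.0 * np.pi * y)
    return np.maximum(base + ridges, 0.0)


def default_world(n_site_rows: int = 24, n_site_cols: int = 24, core_weight: float = 2.5) -> SimWorld:
    """Build the default Gulf-like world.

    Candidate fishing sites form an ``n_site_rows x n_site_cols`` lattice over
    the shelf band; sites inside the core rectangle (the area later closed)
    carry ``core_weight`` times the sampling weight of outside sites, so the
    closure covers the fleet's most-used cells by construction.
    """
    lon_min, lon_max, lat_min, lat_max = -88.0, -83.0, 24.0, 28.5
    port = (-85.5, 28.2)
    closure = box(-86.8, 25.3, -85.0, 26.6)
    # shelf band where fishing happens (away from port and from the edges)
    slon = np.linspace(-87.6, -83.4, n_site_cols)
    slat = np.linspace(24.6, 27.4, n_site_rows)
    gx, gy = np.meshgrid(slon, slat)
    site_lon = gx.ravel()
    site_lat = gy.ravel()
    inside = shapely_contains_xy(closure, site_lon, site_lat)
    weight = np.where(inside, core_weight, 1.0)
    weight = weight / weight.sum()
    return SimWorld(
        lon_min=lon_min,
        lon_max=lon_max,
        lat_min=lat_min,
        lat_max=lat_max,
        port=port,
        closure=closure,
        depth_fn=_default_depth,
        site_lon=site_lon,
        site_lat=site_lat,
        site_weight=weight,
    )
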