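"""Spherical geometry helpers shared across the pipeline.

All coordinates are decimal degrees on WGS84 treated as a sphere of
authalic radius; for range-size features at the scales relevant to Red
List criteria (EOO/AOO up to a few thousand km) the spherical
approximation is well inside the 1% tolerance used by the tests.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # authalic mean radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_min_neighbor_km(lons, lats):
    """For each point, the minimum great-circle distance to any other point."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    if n < 2:
        return np.full(n, np.nan)
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


class EqualAreaProjection:
    """Cylindrical equal-area projection (Lambert) in km.

    Centered on ``lon0`` with standard parallel ``lat_ts``:

        x = R (lambda - lambda0) cos(phi_ts)
        y = R sin(phi) / cos(phi_ts)

    The map is exactly area-preserving on the sphere, which is all the
    EOO/AOO computations need; shape distortion away from the standard
    parallel is irrelevant to areas.
    """

    def __init__(self, lon0: float, lat_ts: float):
        self.lon0 = float(lon0)
        self.lat_ts = float(lat_ts)
        self._cos_ts = np.cos(np.radians(lat_ts))
        if self._cos_ts < 1e-9:
            # standard parallel at a pole degenerates; fall back to equator
            self._cos_ts = 1.0
            self.lat_ts = 0.0

    @classmethod
    def for_points(cls, lons, lats) -> "EqualAreaProjection":
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        # circular mean of longitudes avoids antimeridian artifacts
        lon0 = np.degrees(np.arctan2(np.mean(np.sin(np.radians(lons))), np.mean(np.cos(np.radians(lons)))))
        return cls(lon0=lon0, lat_ts=float(np.mean(lats)))

    def forward(self, lons, lats):
        """Degrees -> (x_km, y_km)."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        dlon = (lons - self.lon0 + 180.0) % 360.0 - 180.0
        x = EARTH_RADIUS_KM * np.radians(dlon) * self._cos_ts
        y = EARTH_RADIUS_KM * np.sin(np.radians(lats)) / self._cos_ts
        return x, y

    def inverse(self, x, y):
        """(x_km, y_km) -> degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_KM * self._cos_ts))
        lat = np.degrees(np.arcsin(np.clip(y * self._cos_ts / EARTH_RADIUS_KM, -1.0, 1.0)))
        return lon, lat


def local_tangent_offset(lon, lat, dx_km, dy_km):
    """Displace a point by (dx, dy) km on the local tangent plane."""
    lat2 = lat + np.degrees(np.asarray(dy_km) / EARTH_RADIUS_KM)
    lon2 = lon + np.degrees(np.asarray(dx_km) / (EARTH_RADIUS_KM * np.cos(np.radians(lat))))
    return lon2, lat2
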