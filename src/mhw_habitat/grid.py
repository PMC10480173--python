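"""Regular lat/lon grid geometry and spherical distance helpers.

All rasters in this package live on a regular geographic grid whose
coordinates are **cell centers**; a cell spans ``[center - res/2,
center + res/2)`` in both axes (half-open), which makes point-to-cell
assignment unambiguous.  Longitudes are restricted to ``[-180, 180)`` and
domains may not straddle the antimeridian, so planar convex hulls and
arithmetic means of longitudes are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: km per degree of latitude (and of longitude at the equator).
KM_PER_DEG = 111.195

#: Mean Earth radius used for great-circle distances, km.
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid defined by outer bounds and a resolution.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max:
        Outer edges of the domain in decimal degrees.
    res:
        Cell size in degrees (same in both axes).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    res: float

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError("grid resolution must be positive")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("grid bounds must satisfy min < max")
        if self.lon_min < -180.0 or self.lon_max > 180.0:
            raise ValueError(
                "longitudes must lie in [-180, 180); domains straddling the "
                "antimeridian are not supported"
            )
        if self.lat_min < -90.0 or self.lat_max > 90.0:
            raise ValueError("latitudes must lie in [-90, 90]")

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.res))

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.res))

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, strictly increasing."""
        return self.lon_min + self.res * (np.arange(self.nlon) + 0.5)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, strictly increasing."""
        return self.lat_min + self.res * (np.arange(self.nlat) + 0.5)

    def point_to_cell(self, lon, lat):
        """Map points to ``(ilat, ilon)`` indices under the half-open rule.

        Points outside the domain get index -1 in the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ilon = np.floor((lon - self.lon_min) / self.res).astype(int)
        ilat = np.floor((lat - self.lat_min) / self.res).astype(int)
        ilon = np.where((ilon >= 0) & (ilon < self.nlon), ilon, -1)
        ilat = np.where((ilat >= 0) & (ilat < self.nlat), ilat, -1)
        return ilat, ilon

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell area on the sphere, shape ``(nlat, nlon)``.

        Uses the cos-latitude approximation ``res^2 * (111.195 km/deg)^2 *
        cos(lat_center)``, adequate at sub-degree resolutions.
        """
        row = (self.res * KM_PER_DEG) ** 2 * np.cos(np.deg2rad(self.lats))
        return np.repeat(row[:, None], self.nlon, axis=1)


def grid_from_coords(lats, lons, res: float | None = None) -> GridSpec:
    """Reconstruct a :class:`GridSpec` from cell-center coordinate vectors.

    Resolution is inferred from the coordinate spacing unless given; a
    1 x 1 grid needs it passed explicitly.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if res is None:
        if lats.size > 1:
            res = float(lats[1] - lats[0])
        elif lons.size > 1:
            res = float(lons[1] - lons[0])
        else:
            raise ValueError("cannot infer resolution from a 1x1 grid; pass res")
    return GridSpec(
        lon_min=float(lons[0] - res / 2),
        lon_max=float(lons[-1] + res / 2),
        lat_min=float(lats[0] - res / 2),
        lat_max=float(lats[-1] + res / 2),
        res=res,
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2.

    Returned in compass convention: 0/360 = north, 90 = east, in [0, 360).
    """
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.mod(np.rad2deg(np.arctan2(x, y)), 360.0)


def weighted_quantile(values, q, weights) -> float:
    """Weighted quantile with linear interpolation between midpoints.

    Duplicate values are merged (their weights summed) so the estimator does
    not depend on tie ordering; each distinct value ``v_i`` with total weight
    ``w_i`` then occupies the cumulative-probability position
    ``(cum_i - w_i/2) / sum(w)`` and the quantile interpolates linearly
    between neighbouring positions, clamped to the extreme values outside
    them.  With equal weights on distinct values this is the Hazen
    (midpoint) estimator, ``numpy.quantile(..., method="hazen")``.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_quantile of an empty set")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative with positive sum")
    v, inverse = np.unique(values, return_inverse=True)
    w = np.bincount(inverse, weights=weights)
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(q, positions, v))
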