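"""Daily binary core habitat and event-level range-shift metrics.

Continuous suitability is reclassified into daily binary *core habitat*
with a species-specific threshold: the 50% quantile (configurable) of the
model's predictions back at the true presence points, so a cell is core
habitat on a day iff its suitability meets or exceeds what the model
assigns to the median occupied location.  Missing cells (outside the
training hull) are never core habitat.

From each daily mask three quantities are computed, all area-weighted by
the spherical cell area (res^2 * 111.195^2 * cos latitude, km^2):

* center of gravity (COG): the weighted mean lon/lat of core cells;
* range extent: the weighted north-south interquartile range of core-cell
  latitudes times the weighted east-west IQR of longitudes, in degrees^2 —
  IQRs rather than absolute ranges so single outlying pixels and hull
  truncation do not dominate;
* core area: the summed cell areas, km^2.

Event impacts are expressed against a seasonal climatological baseline:
daily stats are averaged over the event window and over the baseline
window (zero-area days excluded, count reported), and the event summary
holds the COG displacement as a great-circle distance (haversine,
R = 6371 km) and initial compass bearing, plus range-extent and area
percent changes relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import (
    GridSpec,
    grid_from_coords,
    haversine_km,
    initial_bearing_deg,
    weighted_quantile,
)

STAT_COLUMNS = ("cog_lon", "cog_lat", "iqr_ns", "iqr_ew", "extent_deg2", "area_km2")


@dataclass
class CoreHabitat:
    """Daily boolean core-habitat rasters with their validity (hull) mask."""

    mask: xr.DataArray  # bool, dims (time, lat, lon)
    valid: xr.DataArray  # bool, dims (lat, lon); False where suitability missing
    threshold: float
    species: str = ""

    @property
    def grid(self) -> GridSpec:
        return grid_from_coords(
            self.mask["lat"].values,
            self.mask["lon"].values,
            res=self.mask.attrs.get("resolution_deg"),
        )


def compute_threshold(presence_predictions, quantile: float = 0.5) -> float:
    """Species-specific core-habitat threshold.

    The ``quantile``-th quantile (linear interpolation) of predicted
    suitability at true presence points only.  quantile=0.5 keeps the top
    half of predicted presence values as core; more conservative choices
    (e.g. 0.75) can empty the core entirely during extreme events.
    """
    p = np.asarray(presence_predictions, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no presence predictions to compute a threshold from")
    return float(np.quantile(p, quantile))


def binarize(cube: xr.DataArray, threshold: float, species: str = "") -> CoreHabitat:
    """Reclassify a suitability cube into daily binary core habitat.

    Ties are core (``>=`` threshold); missing suitability is never core and
    stays flagged missing via the validity mask.
    """
    if threshold < 0:
        # values above 1 are allowed as an explicit "empty mask" probe
        raise ValueError("threshold must be non-negative")
    finite = np.isfinite(cube.values)
    mask = xr.DataArray(
        finite & (np.nan_to_num(cube.values, nan=-np.inf) >= threshold),
        dims=cube.dims,
        coords=cube.coords,
    )
    if "resolution_deg" in cube.attrs:
        mask.attrs["resolution_deg"] = cube.attrs["resolution_deg"]
    valid = xr.DataArray(
        finite.all(axis=0) if finite.ndim == 3 else finite,
        dims=("lat", "lon"),
        coords={"lat": cube["lat"], "lon": cube["lon"]},
    )
    return CoreHabitat(mask=mask, valid=valid, threshold=float(threshold), species=species)


def _single_day_stats(day_mask: np.ndarray, lons, lats, areas) -> dict:
    idx = np.flatnonzero(day_mask.ravel())
    if idx.size == 0:
        return {c: np.nan for c in STAT_COLUMNS}
    ilat, ilon = np.divmod(idx, len(lons))
    w = areas.ravel()[idx]
    cell_lons = lons[ilon]
    cell_lats = lats[ilat]
    wsum = w.sum()
    cog_lon = float(np.sum(w * cell_lons) / wsum)
    cog_lat = float(np.sum(w * cell_lats) / wsum)
    iqr_ns = weighted_quantile(cell_lats, 0.75, w) - weighted_quantile(cell_lats, 0.25, w)
    iqr_ew = weighted_quantile(cell_lons, 0.75, w) - weighted_quantile(cell_lons, 0.25, w)
    return {
        "cog_lon": cog_lon,
        "cog_lat": cog_lat,
        "iqr_ns": iqr_ns,
        "iqr_ew": iqr_ew,
        "extent_deg2": iqr_ns * iqr_ew,
        "area_km2": float(wsum),
    }


def daily_stats(core: CoreHabitat, area_weighted: bool = True) -> pd.DataFrame:
    """Per-day COG, IQR extents, and area for a core-habitat stack.

    Zero-area days yield all-missing rows (COG and IQR are undefined on an
    empty mask).  ``area_weighted=False`` switches to unweighted cell means
    and quantiles, for sensitivity checks.
    """
    grid = core.grid
    lons = core.mask["lon"].values
    lats = core.mask["lat"].values
    areas = grid.cell_areas_km2()
    if not area_weighted:
        areas = np.ones_like(areas)
    records = []
    for t in range(core.mask.sizes["time"]):
        records.append(_single_day_stats(core.mask.values[t], lons, lats, areas))
    df = pd.DataFrame.from_records(records, index=pd.DatetimeIndex(core.mask["time"].values))
    df.index.name = "date"
    return df


@dataclass
class EventSummary:
    """Event-versus-baseline impact metrics for one species and event."""

    species: str
    event: str
    displacement_km: float
    bearing_deg: float  # compass: 0/360 = N, 90 = E
    extent_change_pct: float
    area_change_pct: float
    baseline_mean: pd.Series
    event_mean: pd.Series
    n_event_days: int
    n_baseline_days: int
    n_zero_area_dropped: int


def _window_mean(stats: pd.DataFrame, window: tuple[str, str] | pd.DatetimeIndex):
    if isinstance(window, tuple):
        sub = stats.loc[(stats.index >= pd.Timestamp(window[0]))
                        & (stats.index <= pd.Timestamp(window[1]))]
    else:
        sub = stats.loc[stats.index.isin(pd.DatetimeIndex(window))]
    nonzero = sub.dropna(subset=["area_km2"])
    return nonzero.mean(), len(nonzero), len(sub) - len(nonzero)


def summarize_event(
    stats: pd.DataFrame,
    event_window,
    baseline_window,
    species: str = "",
    event_name: str = "",
) -> EventSummary:
    """Average daily stats over the two windows and form the four metrics.

    Windows are ``(start, end)`` date tuples (inclusive) or explicit date
    indexes; the baseline normally *includes* the event days, mirroring a
    climatology computed over all years.  Zero-area days are dropped from
    both means (their count is reported), since COG and IQR are undefined
    there.  A zero baseline extent or area makes the percent change
    undefined and raises, pointing at the threshold choice.
    """
    ev_mean, n_ev, drop_ev = _window_mean(stats, event_window)
    bl_mean, n_bl, drop_bl = _window_mean(stats, baseline_window)
    if n_ev == 0 or n_bl == 0:
        raise ValueError(
            "event or baseline window has no days with core habitat; "
            "lower the threshold quantile"
        )
    if bl_mean["extent_deg2"] == 0 or bl_mean["area_km2"] == 0:
        raise ValueError(
            "baseline range extent or area is zero: percent change undefined; "
            "lower the threshold quantile"
        )
    same_cog = (ev_mean["cog_lon"] == bl_mean["cog_lon"]) and (
        ev_mean["cog_lat"] == bl_mean["cog_lat"]
    )
    if same_cog:
        dist, bearing = 0.0, 0.0
    else:
        dist = float(
            haversine_km(bl_mean["cog_lon"], bl_mean["cog_lat"],
                         ev_mean["cog_lon"], ev_mean["cog_lat"])
        )
        bearing = float(
            initial_bearing_deg(bl_mean["cog_lon"], bl_mean["cog_lat"],
                                ev_mean["cog_lon"], ev_mean["cog_lat"])
        )
    return EventSummary(
        species=species,
        event=event_name,
        displacement_km=dist,
        bearing_deg=bearing,
        extent_change_pct=100.0 * (ev_mean["extent_deg2"] / bl_mean["extent_deg2"] - 1.0),
        area_change_pct=100.0 * (ev_mean["area_km2"] / bl_mean["area_km2"] - 1.0),
        baseline_mean=bl_mean,
        event_mean=ev_mean,
        n_event_days=n_ev,
        n_baseline_days=n_bl,
        n_zero_area_dropped=drop_ev + drop_bl,
    )


def summaries_to_frame(summaries: list[EventSummary]) -> pd.DataFrame:
    rows = [
        {
            "species": s.species,
            "event": s.event,
            "displacement_km": s.displacement_km,
            "bearing_deg": s.bearing_deg,
            "extent_change_pct": s.extent_change_pct,
            "area_change_pct": s.area_change_pct,
            "baseline_area_km2": s.baseline_mean["area_km2"],
            "event_area_km2": s.event_mean["area_km2"],
            "baseline_extent_deg2": s.baseline_mean["extent_deg2"],
            "event_extent_deg2": s.event_mean["extent_deg2"],
            "n_event_days": s.n_event_days,
            "n_baseline_days": s.n_baseline_days,
            "n_zero_area_dropped": s.n_zero_area_dropped,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def write_masks(core: CoreHabitat, path) -> None:
    """Persist daily masks as NetCDF uint8 (1 core, 0 not, 255 missing)."""
    arr = core.mask.values.astype(np.uint8)
    arr = np.where(core.valid.values[None, :, :], arr, np.uint8(255))
    da = xr.DataArray(arr, dims=core.mask.dims, coords=core.mask.coords, name="core_habitat")
    da.attrs["threshold"] = core.threshold
    da.attrs["species"] = core.species
    da.attrs["missing_value"] = 255
    da.to_netcdf(path)
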