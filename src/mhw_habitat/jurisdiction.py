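"""Cross-jurisdictional accounting of core habitat.

Daily core-habitat area is partitioned across maritime-jurisdiction
polygons (EEZ-style zones plus a residual high-seas zone) by assigning
each grid cell to the zone containing its center, then summing the same
cos-latitude cell areas used by the habitat metrics — so zone areas sum
exactly to the total core area each day.  Event anomalies per zone are
percent changes of window-mean area versus the climatological baseline;
zones with zero baseline area report an explicitly undefined anomaly
(NaN), never 0 or infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import GridSpec
from .habitat_metrics import CoreHabitat
from .synthetic import HIGH_SEAS, Zone

logger = logging.getLogger(__name__)


@dataclass
class CellZoneMap:
    """Cached cell-to-zone assignment for one grid and polygon set."""

    zone_names: list[str]  # sorted; index i corresponds to code i
    codes: np.ndarray  # int (nlat, nlon), index into zone_names
    n_boundary_cells: int


def assign_cells(grid: GridSpec, zones: list[Zone]) -> CellZoneMap:
    """Assign every grid cell to exactly one zone by its center point.

    Cells covered by no polygon fall to the residual ``high_seas`` zone.
    A cell center lying on a shared boundary is assigned to the
    lexicographically first zone; such cells are counted and logged.
    """
    names = sorted({z.name for z in zones} | {HIGH_SEAS})
    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats)
    codes = np.full(lon2d.shape, names.index(HIGH_SEAS), dtype=int)
    hits = np.zeros(lon2d.shape, dtype=int)
    for z in sorted(zones, key=lambda z: z.name):
        inside = shapely.intersects_xy(z.polygon, lon2d, lat2d)
        first_hit = inside & (hits == 0)
        codes[first_hit] = names.index(z.name)
        hits += inside
    n_boundary = int((hits > 1).sum())
    if n_boundary:
        logger.info("assign_cells: %d cell center(s) on shared boundaries", n_boundary)
    return CellZoneMap(zone_names=names, codes=codes, n_boundary_cells=n_boundary)


def daily_zone_areas(core: CoreHabitat, zone_map: CellZoneMap) -> pd.DataFrame:
    """Per-day core-habitat area (km^2) in each zone; columns sum to total."""
    grid = core.grid
    areas = grid.cell_areas_km2()
    n_zones = len(zone_map.zone_names)
    out = np.zeros((core.mask.sizes["time"], n_zones))
    codes = zone_map.codes.ravel()
    flat_areas = areas.ravel()
    for t in range(core.mask.sizes["time"]):
        sel = core.mask.values[t].ravel()
        out[t] = np.bincount(codes[sel], weights=flat_areas[sel], minlength=n_zones)
    return pd.DataFrame(
        out,
        index=pd.DatetimeIndex(core.mask["time"].values, name="date"),
        columns=zone_map.zone_names,
    )


def zonal_ledger(
    zone_areas: pd.DataFrame,
    events: list[tuple[str, str, str]],
    baseline_window: tuple[str, str],
    species: str = "",
) -> pd.DataFrame:
    """Window means and percent-change anomalies per zone and event.

    ``events`` are ``(name, start, end)`` tuples; the baseline window is a
    ``(start, end)`` tuple that normally spans all years of the record.
    Returns a tidy frame ``species, zone, event, baseline_km2, event_km2,
    anomaly_pct`` including every zone (zeros included); anomaly is NaN
    where the baseline mean area is zero.
    """
    idx = zone_areas.index
    bl = zone_areas.loc[
        (idx >= pd.Timestamp(baseline_window[0])) & (idx <= pd.Timestamp(baseline_window[1]))
    ]
    if bl.empty:
        raise ValueError("baseline window not covered by the daily masks")
    bl_mean = bl.mean()
    rows = []
    for name, start, end in events:
        ev = zone_areas.loc[(idx >= pd.Timestamp(start)) & (idx <= pd.Timestamp(end))]
        if ev.empty:
            raise ValueError(f"event {name!r} window not covered by the daily masks")
        ev_mean = ev.mean()
        for zone in zone_areas.columns:
            b, e = float(bl_mean[zone]), float(ev_mean[zone])
            anom = 100.0 * (e - b) / b if b > 0 else np.nan
            rows.append(
                {
                    "species": species,
                    "zone": zone,
                    "event": name,
                    "baseline_km2": b,
                    "event_km2": e,
                    "anomaly_pct": anom,
                }
            )
    return pd.DataFrame(rows)


def largest_shift_summary(ledger: pd.DataFrame, event_order: list[str] | None = None) -> pd.DataFrame:
    """Per-species largest percent gain and loss over all (zone, event) pairs.

    Ties break to the earlier event (by ``event_order``, defaulting to
    first appearance in the ledger) and then to the lexicographically first
    zone name.  Undefined anomalies (NaN) never win.
    """
    if event_order is None:
        event_order = list(dict.fromkeys(ledger["event"]))
    ev_rank = {e: i for i, e in enumerate(event_order)}
    rows = []
    for species, sub in ledger.groupby("species", sort=True):
        defined = sub.dropna(subset=["anomaly_pct"]).copy()
        if defined.empty:
            raise ValueError(f"no defined anomalies for species {species!r}")
        defined["_rank"] = defined["event"].map(ev_rank)
        defined = defined.sort_values(["_rank", "zone"], kind="stable")
        gain = defined.loc[defined["anomaly_pct"].idxmax()]
        loss = defined.loc[defined["anomaly_pct"].idxmin()]
        rows.append(
            {
                "species": species,
                "gain_zone": gain["zone"],
                "gain_event": gain["event"],
                "gain_pct": gain["anomaly_pct"],
                "loss_zone": loss["zone"],
                "loss_event": loss["event"],
                "loss_pct": loss["anomaly_pct"],
            }
        )
    return pd.DataFrame(rows)
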