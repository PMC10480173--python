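"""Presence/pseudo-absence construction and kernel-density groupings.

Presence-only telemetry cannot be modelled without a contrast class.
Following standard species-distribution-modelling practice, one background
pseudo-absence is drawn per presence *on the same date*, uniformly over the
background domain (by default the species' convex hull of presences,
rasterized to grid cells), excluding the cells that hold a presence of that
species on that date.  This yields an exact 1:1 class balance and an
identical date distribution for the two classes, so the model contrasts
*where* the animals were against where they could have been on the same day.

Covariate matching assigns each point the value of its containing grid cell
on its date (half-open cell convention), plus day-of-year; rows with any
missing covariate or falling outside the grid/date range are dropped with a
warning, never silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from shapely.geometry import MultiPoint

from .grid import GridSpec, grid_from_coords

logger = logging.getLogger(__name__)

#: Name of the derived temporal covariate appended during matching.
DAY_OF_YEAR = "day_of_year"


def presence_hull(lon, lat):
    """Minimum convex hull of points, on lon/lat treated as planar."""
    pts = MultiPoint(list(zip(np.asarray(lon, float), np.asarray(lat, float))))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("presences are collinear or too few for a convex hull")
    return hull


def rasterize_mask(grid: GridSpec, polygon) -> np.ndarray:
    """Boolean (nlat, nlon) mask of cells whose centers fall in ``polygon``."""
    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats)
    # intersects = covers for points: boundary cells included
    return shapely.intersects_xy(polygon, lon2d, lat2d)


def sample_pseudo_absences(
    telemetry: pd.DataFrame,
    grid: GridSpec,
    domain: str | np.ndarray = "hull",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one same-date background point per presence.

    Parameters
    ----------
    telemetry:
        Presence fixes with columns ``species, date, lon, lat``.
    grid:
        The analysis grid; pseudo-absences are placed at cell centers.
    domain:
        ``"hull"`` (default) restricts background cells to the species'
        convex hull of presences; ``"full"`` uses the whole grid; a boolean
        ``(nlat, nlon)`` array gives an explicit domain mask.
    seed:
        RNG seed; fixed seed gives identical coordinates across runs.

    Returns
    -------
    DataFrame with columns ``species, date, lon, lat, label`` where label is
    1 for presences and 0 for pseudo-absences, balanced 1:1 per species and
    matched date-for-date.
    """
    if telemetry.empty:
        raise ValueError("telemetry is empty")
    rng = np.random.default_rng(seed)
    out = []
    for species, sp_df in telemetry.groupby("species", sort=True):
        if isinstance(domain, np.ndarray):
            dom = domain.astype(bool)
        elif domain == "full":
            dom = np.ones((grid.nlat, grid.nlon), dtype=bool)
        elif domain == "hull":
            dom = rasterize_mask(grid, presence_hull(sp_df["lon"], sp_df["lat"]))
        else:
            raise ValueError(f"unknown domain {domain!r}")
        if not dom.any():
            raise ValueError("background domain mask is empty")
        dom_flat = np.flatnonzero(dom.ravel())

        pres = sp_df.copy()
        pres["label"] = 1
        out.append(pres[["species", "date", "lon", "lat", "label"]])

        for date, day_df in sp_df.groupby("date", sort=True):
            ilat, ilon = grid.point_to_cell(day_df["lon"].to_numpy(), day_df["lat"].to_numpy())
            occupied = set((ilat * grid.nlon + ilon).tolist())
            avail = dom_flat[~np.isin(dom_flat, list(occupied))]
            if avail.size == 0:
                raise ValueError(
                    f"no background cells available for {species!r} on "
                    f"{pd.Timestamp(date).date()}: presences occupy the whole domain"
                )
            cells = rng.choice(avail, size=len(day_df), replace=True)
            alat, alon = np.divmod(cells, grid.nlon)
            out.append(
                pd.DataFrame(
                    {
                        "species": species,
                        "date": date,
                        "lon": grid.lons[alon],
                        "lat": grid.lats[alat],
                        "label": 0,
                    }
                )
            )
    res = pd.concat(out, ignore_index=True)
    res["date"] = pd.to_datetime(res["date"])
    return res


def match_covariates(points: pd.DataFrame, env: xr.Dataset) -> pd.DataFrame:
    """Attach each point the covariate vector of its cell on its date.

    Adds all covariates in ``env`` plus ``day_of_year``.  Points outside the
    grid or the date axis, or with any missing covariate, are dropped; the
    drop count is logged and warned about (never silent).
    """
    grid = grid_from_coords(env["lat"].values, env["lon"].values,
                            res=env.attrs.get("resolution_deg"))
    dates = pd.DatetimeIndex(env["time"].values)
    date_pos = pd.Series(np.arange(len(dates)), index=dates)

    df = points.copy()
    n0 = len(df)
    ilat, ilon = grid.point_to_cell(df["lon"].to_numpy(), df["lat"].to_numpy())
    tpos = date_pos.reindex(pd.to_datetime(df["date"])).to_numpy()
    ok = (ilat >= 0) & (ilon >= 0) & ~pd.isna(tpos)
    if not ok.all():
        warnings.warn(
            f"match_covariates: dropping {int((~ok).sum())} point(s) outside "
            "the grid or date range",
            stacklevel=2,
        )
    df = df.loc[ok].copy()
    ilat, ilon, tpos = ilat[ok], ilon[ok], tpos[ok].astype(int)

    for name, da in env.data_vars.items():
        df[name] = da.values[tpos, ilat, ilon]
    df[DAY_OF_YEAR] = pd.to_datetime(df["date"]).dt.dayofyear.to_numpy()

    cov_cols = list(env.data_vars) + [DAY_OF_YEAR]
    missing = df[cov_cols].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"match_covariates: dropping {int(missing.sum())} row(s) with "
            "missing covariates",
            stacklevel=2,
        )
    df = df.loc[~missing].reset_index(drop=True)
    logger.info("match_covariates: %d -> %d rows", n0, len(df))

    if "label" in df.columns:
        counts = df.groupby("species")["label"].agg(["sum", "count"])
        ratio = counts["sum"] / (counts["count"] - counts["sum"]).replace(0, np.nan)
        bad = ratio[(ratio - 1.0).abs() > 0.05]
        for sp, r in bad.items():
            warnings.warn(
                f"presence:absence ratio for {sp!r} is {r:.3f} after drops "
                "(departs from 1:1 by >5%)",
                stacklevel=2,
            )
    return df


@dataclass
class KernelSummary:
    """Group-level kernel density and its upper-quantile contour mask."""

    group: str
    density: xr.DataArray  # (lat, lon), integrates to ~1 over the plane
    contour_mask: xr.DataArray  # bool (lat, lon)
    quantile: float
    subsample_size: int
    species: tuple[str, ...]


def kernel_group_summary(
    telemetry: pd.DataFrame,
    groups: dict[str, str],
    grid: GridSpec,
    q: float = 0.75,
    seed: int = 0,
) -> dict[str, KernelSummary]:
    """Group kernel densities with upper-quantile contours.

    Each species in a group is randomly subsampled to the group's smallest
    per-species record count so no species dominates; a Gaussian KDE
    (Silverman bandwidth) is fitted per species and the group density is
    their mean — so a group of species with identical distributions has the
    same kernel as any one of them.  The contour mask keeps cells whose
    density is at least the ``q``-th quantile of the group density
    evaluated at the pooled subsampled points themselves — the region
    holding the top ``(1-q)`` fraction of points by local density.
    """
    from scipy.stats import gaussian_kde

    rng = np.random.default_rng(seed)
    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats)
    grid_xy = np.vstack([lon2d.ravel(), lat2d.ravel()])

    out: dict[str, KernelSummary] = {}
    for group in sorted(set(groups.values())):
        members = sorted(sp for sp, g in groups.items() if g == group)
        tabs = [telemetry[telemetry["species"] == sp] for sp in members]
        if any(t.empty for t in tabs) or not members:
            raise ValueError(f"group {group!r} has a member with no telemetry")
        n_sub = min(len(t) for t in tabs)
        subsamples = []
        for t in tabs:
            idx = rng.choice(len(t), size=n_sub, replace=False)
            subsamples.append(t.iloc[np.sort(idx)][["lon", "lat"]].to_numpy().T)
        kdes = [gaussian_kde(s, bw_method="silverman") for s in subsamples]
        pts = np.concatenate(subsamples, axis=1)  # (2, n_species * n_sub)
        dens_grid = np.mean([k(grid_xy) for k in kdes], axis=0).reshape(grid.nlat, grid.nlon)
        dens_pts = np.mean([k(pts) for k in kdes], axis=0)
        thr = float(np.quantile(dens_pts, q))
        density = xr.DataArray(
            dens_grid, dims=("lat", "lon"), coords={"lat": grid.lats, "lon": grid.lons}
        )
        out[group] = KernelSummary(
            group=group,
            density=density,
            contour_mask=density >= thr,
            quantile=q,
            subsample_size=n_sub,
            species=tuple(members),
        )
    return out


def write_occurrences(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
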