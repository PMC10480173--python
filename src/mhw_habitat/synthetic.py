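"""Synthetic telemetry, ocean-covariate cubes, and jurisdiction polygons.

This module stands in for the data a marine-heatwave habitat analysis would
normally ingest — satellite/reanalysis covariate fields, animal-borne tag
tracks, and maritime-boundary polygons — but with a fully known ground
truth: the species-environment relationship is an explicit logistic
function of the covariates, heatwave anomalies are injected additively over
stated windows and boxes, and range shifts (habitat translation and/or
isotropic scaling during events) are injected by moving the habitat-defining
covariate features.  Every downstream stage of the pipeline therefore has a
recoverable answer.

Environmental fields are built as

    baseline(lon, lat) + seasonal cycle(doy) + event anomaly + N(0, sd)

where the baseline is a sum of a linear trend surface and Gaussian bumps.
During a declared event window, covariates marked ``shiftable`` have their
bumps translated by the scenario's shift vector and their widths multiplied
by its scale factor; this is what makes a known displacement/expansion of
true habitat flow through the whole pipeline.

Noise is i.i.d. Gaussian per cell-day; there is no spatial or temporal
autocorrelation, mesoscale structure, or mechanistic animal movement.
Telemetry is a daily cell-weighted multinomial draw from the true
suitability surface: only the presence *distribution* matters downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import box as shapely_box, mapping, shape

from .grid import GridSpec

# Stage constants for deriving per-stage RNG streams from one master seed;
# see also reporting.stage_seed.
_STAGE_ENV = 1
_STAGE_TELEMETRY = 2

DAYS_PER_YEAR = 365.25


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class GaussianBump:
    """An elliptical Gaussian feature ``amp * exp(-((dlon/slon)^2 + (dlat/slat)^2)/2)``."""

    amplitude: float
    lon0: float
    lat0: float
    sigma_lon: float
    sigma_lat: float


@dataclass(frozen=True)
class CovariateSpec:
    """One environmental covariate: baseline surface, seasonality, noise.

    ``shiftable=True`` marks the covariate as habitat-defining: its Gaussian
    bumps are translated/scaled during event windows according to the
    scenario's :class:`ShiftSpec`.
    """

    name: str
    units: str = ""
    constant: float = 0.0
    lon_gradient: float = 0.0
    lat_gradient: float = 0.0
    bumps: tuple[GaussianBump, ...] = ()
    seasonal_amplitude: float = 0.0
    seasonal_peak_doy: float = 227.0  # mid-August, northern-hemisphere summer
    noise_sd: float = 0.0
    shiftable: bool = False


@dataclass(frozen=True)
class BoxAnomaly:
    """Additive event anomaly: ``amplitude`` inside the lon/lat box (whole domain if None)."""

    covariate: str
    amplitude: float
    lon_min: float | None = None
    lon_max: float | None = None
    lat_min: float | None = None
    lat_max: float | None = None


@dataclass(frozen=True)
class EventWindow:
    name: str
    start: str  # ISO date, inclusive
    end: str  # ISO date, inclusive
    anomalies: tuple[BoxAnomaly, ...] = ()


@dataclass(frozen=True)
class ShiftSpec:
    """Range shift injected during events: translation in degrees, isotropic scale."""

    dlon: float = 0.0
    dlat: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class TrackSpec:
    """Per-species telemetry volume: individuals and daily fix rate."""

    species: str
    n_individuals: int = 5
    points_per_day: int = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of a synthetic world.

    ``suitability`` maps covariate names to logistic weights; the true
    suitability surface is ``expit(intercept + sum_c w_c * x_c)`` evaluated
    on the generated fields.  ``months`` restricts the daily time axis to a
    seasonal window (the analysis season), keeping cubes desk-sized.
    """

    grid: GridSpec
    start_date: str
    end_date: str
    covariates: tuple[CovariateSpec, ...]
    suitability: dict[str, float]
    intercept: float = 0.0
    events: tuple[EventWindow, ...] = ()
    shift: ShiftSpec = ShiftSpec()
    species: tuple[TrackSpec, ...] = (TrackSpec("species_a"),)
    months: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        start = np.datetime64(self.start_date)
        end = np.datetime64(self.end_date)
        if start > end:
            raise ConfigurationError("start_date must not exceed end_date")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        for cov, w in self.suitability.items():
            if cov not in names:
                raise ConfigurationError(f"suitability weight for unknown covariate {cov!r}")
            if not np.isfinite(w):
                raise ConfigurationError(f"non-finite suitability weight for {cov!r}")
        for ev in self.events:
            if np.datetime64(ev.start) < start or np.datetime64(ev.end) > end:
                raise ConfigurationError(
                    f"event {ev.name!r} window lies outside the scenario date range"
                )
            for an in ev.anomalies:
                if an.covariate not in names:
                    raise ConfigurationError(
                        f"event {ev.name!r} anomaly targets unknown covariate {an.covariate!r}"
                    )

    @property
    def dates(self) -> pd.DatetimeIndex:
        days = pd.date_range(self.start_date, self.end_date, freq="D")
        if self.months is not None:
            days = days[days.month.isin(self.months)]
        return days

    def event_day_mask(self, dates: pd.DatetimeIndex) -> np.ndarray:
        mask = np.zeros(len(dates), dtype=bool)
        for ev in self.events:
            mask |= (dates >= pd.Timestamp(ev.start)) & (dates <= pd.Timestamp(ev.end))
        return mask

    # ---- declarative file round-trip -------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        g = d["grid"]
        grid = GridSpec(g["lon_min"], g["lon_max"], g["lat_min"], g["lat_max"], g["res"])
        covs = tuple(
            CovariateSpec(
                name=c["name"],
                units=c.get("units", ""),
                constant=c.get("constant", 0.0),
                lon_gradient=c.get("lon_gradient", 0.0),
                lat_gradient=c.get("lat_gradient", 0.0),
                bumps=tuple(GaussianBump(**b) for b in c.get("bumps", [])),
                seasonal_amplitude=c.get("seasonal_amplitude", 0.0),
                seasonal_peak_doy=c.get("seasonal_peak_doy", 227.0),
                noise_sd=c.get("noise_sd", 0.0),
                shiftable=c.get("shiftable", False),
            )
            for c in d["covariates"]
        )
        events = tuple(
            EventWindow(
                name=e["name"],
                start=e["start"],
                end=e["end"],
                anomalies=tuple(BoxAnomaly(**a) for a in e.get("anomalies", [])),
            )
            for e in d.get("events", [])
        )
        shift = ShiftSpec(**d.get("shift", {}))
        species = tuple(TrackSpec(**s) for s in d.get("species", [{"species": "species_a"}]))
        months = tuple(d["months"]) if d.get("months") else None
        return cls(
            grid=grid,
            start_date=d["start_date"],
            end_date=d["end_date"],
            covariates=covs,
            suitability=dict(d["suitability"]),
            intercept=d.get("intercept", 0.0),
            events=events,
            shift=shift,
            species=species,
            months=months,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        """Plain-type dict mirroring the declarative file format."""
        from dataclasses import asdict

        d = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _bump_field(bump: GaussianBump, lon2d, lat2d, shift: ShiftSpec | None) -> np.ndarray:
    lon0, lat0 = bump.lon0, bump.lat0
    slon, slat = bump.sigma_lon, bump.sigma_lat
    if shift is not None:
        lon0 += shift.dlon
        lat0 += shift.dlat
        slon *= shift.scale
        slat *= shift.scale
    return bump.amplitude * np.exp(
        -0.5 * (((lon2d - lon0) / slon) ** 2 + ((lat2d - lat0) / slat) ** 2)
    )


def _baseline_surface(cov: CovariateSpec, lon2d, lat2d, shift: ShiftSpec | None) -> np.ndarray:
    out = np.full(lon2d.shape, cov.constant, dtype=float)
    out += cov.lon_gradient * (lon2d - lon2d.mean())
    out += cov.lat_gradient * (lat2d - lat2d.mean())
    for b in cov.bumps:
        out += _bump_field(b, lon2d, lat2d, shift if cov.shiftable else None)
    return out


def generate_environment(config: ScenarioConfig) -> xr.Dataset:
    """Build the daily covariate cube described by ``config``.

    Returns an :class:`xarray.Dataset` with dims ``(time, lat, lon)``, one
    variable per covariate, cell-center coordinates, and per-variable
    ``units`` attributes.  With zero noise the injected anomalies are exact;
    with noise they are recoverable by event-minus-baseline differencing to
    within the usual ``sd / sqrt(n_days)`` Monte-Carlo error.
    """
    grid = config.grid
    dates = config.dates
    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats)
    event_mask = config.event_day_mask(dates)
    doy = dates.dayofyear.to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE_ENV]))
    data = {}
    for cov in config.covariates:
        base = _baseline_surface(cov, lon2d, lat2d, shift=None)
        shifted = (
            _baseline_surface(cov, lon2d, lat2d, shift=config.shift)
            if cov.shiftable
            else base
        )
        cube = np.empty((len(dates), grid.nlat, grid.nlon), dtype=float)
        season = cov.seasonal_amplitude * np.cos(
            2.0 * np.pi * (doy - cov.seasonal_peak_doy) / DAYS_PER_YEAR
        )
        for t in range(len(dates)):
            cube[t] = (shifted if event_mask[t] else base) + season[t]
        for ev in config.events:
            in_ev = (dates >= pd.Timestamp(ev.start)) & (dates <= pd.Timestamp(ev.end))
            for an in ev.anomalies:
                if an.covariate != cov.name:
                    continue
                boxmask = np.ones(lon2d.shape, dtype=bool)
                if an.lon_min is not None:
                    boxmask &= lon2d >= an.lon_min
                if an.lon_max is not None:
                    boxmask &= lon2d < an.lon_max
                if an.lat_min is not None:
                    boxmask &= lat2d >= an.lat_min
                if an.lat_max is not None:
                    boxmask &= lat2d < an.lat_max
                cube[np.asarray(in_ev)] += an.amplitude * boxmask
        if cov.noise_sd > 0:
            cube += rng.normal(0.0, cov.noise_sd, size=cube.shape)
        data[cov.name] = xr.DataArray(
            cube,
            dims=("time", "lat", "lon"),
            coords={"time": dates, "lat": grid.lats, "lon": grid.lons},
            attrs={"units": cov.units},
        )
    ds = xr.Dataset(data)
    ds.attrs["resolution_deg"] = grid.res
    return ds


def true_suitability(config: ScenarioConfig, env: xr.Dataset) -> xr.DataArray:
    """Ground-truth suitability: logistic in the generated covariates."""
    from scipy.special import expit

    logit = xr.zeros_like(env[next(iter(env.data_vars))]) + config.intercept
    for cov, w in config.suitability.items():
        logit = logit + w * env[cov]
    out = xr.apply_ufunc(expit, logit)
    out.name = "suitability"
    return out


def generate_telemetry(config: ScenarioConfig, env: xr.Dataset) -> pd.DataFrame:
    """Sample presence fixes proportional to true suitability.

    Each day, each individual contributes ``points_per_day`` fixes drawn from
    a multinomial over grid cells weighted by that day's true suitability,
    jittered uniformly within the cell so fixes are not all at cell centers
    (the jitter never crosses a cell boundary, so covariate matching is
    exact).  Returns columns ``species, individual, date, lon, lat``.
    """
    grid = config.grid
    dates = pd.DatetimeIndex(env["time"].values)
    suit = true_suitability(config, env).values  # (time, nlat, nlon)
    ncell = grid.nlat * grid.nlon
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE_TELEMETRY]))

    rows = []
    for sp in config.species:
        n_daily = sp.n_individuals * sp.points_per_day
        for t, date in enumerate(dates):
            w = suit[t].ravel()
            w = np.where(np.isfinite(w), np.clip(w, 0.0, None), 0.0)
            total = w.sum()
            if total <= 0:
                raise ValueError(
                    f"all-zero suitability surface for {sp.species!r} on "
                    f"{date.date()}: cannot sample presences"
                )
            cells = rng.choice(ncell, size=n_daily, p=w / total)
            ilat, ilon = np.divmod(cells, grid.nlon)
            jit_lon = rng.uniform(-0.5, 0.5, size=n_daily) * grid.res
            jit_lat = rng.uniform(-0.5, 0.5, size=n_daily) * grid.res
            lons = grid.lons[ilon] + jit_lon
            lats = grid.lats[ilat] + jit_lat
            ind = np.repeat(np.arange(sp.n_individuals), sp.points_per_day)
            for k in range(n_daily):
                rows.append((sp.species, f"{sp.species}_{ind[k]:03d}", date, lons[k], lats[k]))
    df = pd.DataFrame(rows, columns=["species", "individual", "date", "lon", "lat"])
    df["date"] = pd.to_datetime(df["date"])
    return df


@dataclass(frozen=True)
class Zone:
    name: str
    polygon: object  # shapely geometry


#: Reserved name for the residual zone outside all explicit polygons.
HIGH_SEAS = "high_seas"


def generate_jurisdictions(config: ScenarioConfig, n_zones: int = 3) -> list[Zone]:
    """Partition the domain into coastal EEZ-like bands plus high seas.

    The eastern half of the domain is split into ``n_zones`` (3 or 4)
    latitude bands named zone_a (southernmost) upward; the western half is
    the residual ``high_seas``.  The polygons tile the domain exactly.
    """
    if n_zones not in (3, 4):
        raise ConfigurationError("n_zones must be 3 or 4")
    g = config.grid
    lon_split = (g.lon_min + g.lon_max) / 2.0
    edges = np.linspace(g.lat_min, g.lat_max, n_zones + 1)
    zones = [
        Zone(
            name=f"zone_{chr(ord('a') + i)}",
            polygon=shapely_box(lon_split, edges[i], g.lon_max, edges[i + 1]),
        )
        for i in range(n_zones)
    ]
    zones.append(Zone(HIGH_SEAS, shapely_box(g.lon_min, g.lat_min, lon_split, g.lat_max)))
    return zones


# ---- persistence ---------------------------------------------------------


def write_environment(env: xr.Dataset, path) -> None:
    env.to_netcdf(path)


def read_environment(path) -> xr.Dataset:
    return xr.load_dataset(path)


def write_telemetry(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=["species", "individual", "date", "lon", "lat"])


def read_telemetry(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df


def write_jurisdictions(zones: list[Zone], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"zone": z.name},
                "geometry": mapping(z.polygon),
            }
            for z in zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_jurisdictions(path) -> list[Zone]:
    with open(path) as fh:
        fc = json.load(fh)
    return [Zone(f["properties"]["zone"], shape(f["geometry"])) for f in fc["features"]]
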