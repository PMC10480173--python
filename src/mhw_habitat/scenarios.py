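"""Ready-made synthetic scenarios: a Northeast-Pacific-like stated world.

All scenarios share one desk-scale domain — a 10 x 10 degree box at 0.25
degree resolution (40 x 40 cells) off a western coastline, with daily
fields restricted to the August-October analysis season.  Covariates:

* ``sst`` (degC): meridional gradient (warmer south), seasonal cycle
  peaking mid-August, cell-day noise;
* ``sst_sd`` (degC): spatial SST variability, a noisy constant here;
* ``chl`` (mg m-3): low background plus a productive Gaussian patch — the
  habitat-defining feature.  Range shifts are injected by translating
  and/or widening this patch during event windows;
* ``o2`` (mmol m-3), ``sla`` (m), ``mld`` (m): realistic distractor
  covariates that carry no true signal.

True suitability is logistic in chlorophyll (strong) and SST (weak), so a
multivariate model has more to learn from than a temperature-only one.
Telemetry defaults to 5 individuals per species at 1-2 fixes per day,
giving a few thousand presences over a decade of seasons — the order of a
real multi-year tagging programme after track filtering.
"""

from __future__ import annotations

from .grid import GridSpec
from .synthetic import (
    BoxAnomaly,
    CovariateSpec,
    EventWindow,
    GaussianBump,
    ScenarioConfig,
    ShiftSpec,
    TrackSpec,
)

GRID = GridSpec(lon_min=-135.0, lon_max=-125.0, lat_min=32.0, lat_max=42.0, res=0.25)

SEASON = (8, 9, 10)  # August-October, the high-anomaly season

#: The habitat patch: a productive filament in the middle of the domain.
CHL_BUMP = GaussianBump(amplitude=1.5, lon0=-130.5, lat0=36.5, sigma_lon=1.8, sigma_lat=1.8)


def _covariates(chl_noise: float = 0.05) -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec(
            name="sst",
            units="degC",
            constant=16.0,
            lat_gradient=-0.5,
            seasonal_amplitude=2.0,
            seasonal_peak_doy=227.0,
            noise_sd=0.3,
        ),
        CovariateSpec(name="sst_sd", units="degC", constant=0.5, noise_sd=0.05),
        CovariateSpec(
            name="chl",
            units="mg m-3",
            constant=0.1,
            bumps=(CHL_BUMP,),
            noise_sd=chl_noise,
            shiftable=True,
        ),
        CovariateSpec(name="o2", units="mmol m-3", constant=200.0, lat_gradient=2.0, noise_sd=2.0),
        CovariateSpec(name="sla", units="m", constant=0.0, noise_sd=0.03),
        CovariateSpec(name="mld", units="m", constant=30.0, noise_sd=2.0),
    )


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The showcase world: two heatwave seasons inside a 2010-2020 record.

    Both events carry a +2 degC SST anomaly over the eastern half of the
    domain and a modest northwest translation of the habitat patch.  The
    climatological baseline is the full August-October record, so — as in
    any real climatology — it includes the event years.
    """
    events = tuple(
        EventWindow(
            name=f"mhw_{year}",
            start=f"{year}-08-01",
            end=f"{year}-10-31",
            anomalies=(BoxAnomaly(covariate="sst", amplitude=2.0, lon_min=-130.0),),
        )
        for year in (2014, 2015)
    )
    return ScenarioConfig(
        grid=GRID,
        start_date="2010-08-01",
        end_date="2020-10-31",
        months=SEASON,
        covariates=_covariates(),
        suitability={"chl": 2.5, "sst": 0.25},
        intercept=-8.0,
        events=events,
        shift=ShiftSpec(dlon=-1.0, dlat=1.0, scale=1.0),
        species=(
            TrackSpec("thunnus_synthetica", n_individuals=5, points_per_day=1),
            TrackSpec("ardenna_synthetica", n_individuals=5, points_per_day=1),
        ),
        seed=seed,
    )


def displacement_scenario(seed: int = 0, dlon: float = -1.5, dlat: float = 1.5) -> ScenarioConfig:
    """A single 2015 event whose only effect is a known habitat translation.

    Suitability depends on the chlorophyll patch alone, and the patch moves
    by ``(dlon, dlat)`` degrees during the event, so the pipeline should
    recover that displacement at the measurement grid's precision.  The
    baseline is the full 2010-2020 seasonal record including the event
    year, as in a real climatology; with 1 event year in 11 the inclusion
    biases the recovered displacement low by ~9%, well inside a grid cell.
    """
    return ScenarioConfig(
        grid=GRID,
        start_date="2010-08-01",
        end_date="2020-10-31",
        months=SEASON,
        covariates=_covariates(),
        suitability={"chl": 2.5},
        intercept=-4.0,
        events=(EventWindow(name="mhw_2015", start="2015-08-01", end="2015-10-31"),),
        shift=ShiftSpec(dlon=dlon, dlat=dlat, scale=1.0),
        species=(TrackSpec("species_a", n_individuals=5, points_per_day=1),),
        seed=seed,
    )


def expansion_scenario(seed: int = 0, scale: float = 1.5) -> ScenarioConfig:
    """A single 2015 event that isotropically widens the habitat patch.

    The patch's Gaussian widths are multiplied by ``scale`` during the
    event, so every suitability level set — hence the binary core habitat
    and its interquartile extents — scales by the same factor and the true
    range-extent change is exactly ``100 * (scale^2 - 1)`` percent.

    Two deliberate departures from the showcase world make this a test of
    the estimator rather than of two known floors on its precision:

    * the grid is finer (0.1 degree): the quartiles of a core region only
      ~9 cells in radius snap to the cell lattice, and at 0.25 degrees that
      quantization alone moves the extent change by tens of percentage
      points (real basin-scale habitats are far better resolved relative
      to the cell);
    * the distractor covariates carry no spatial gradient: a gradient makes
      them latitude proxies, and a correlative model that learns position
      via a proxy cannot follow the patch when it widens beyond its
      training footprint.
    """
    fine_grid = GridSpec(lon_min=-134.0, lon_max=-126.0, lat_min=32.0, lat_max=40.0, res=0.1)
    bump = GaussianBump(amplitude=1.5, lon0=-130.0, lat0=36.0, sigma_lon=1.5, sigma_lat=1.5)
    covariates = (
        CovariateSpec(
            name="sst",
            units="degC",
            constant=16.0,
            seasonal_amplitude=2.0,
            seasonal_peak_doy=227.0,
            noise_sd=0.3,
        ),
        CovariateSpec(name="sst_sd", units="degC", constant=0.5, noise_sd=0.05),
        # The seasonal chl cycle sweeps the daily core radius through a
        # couple of grid cells each season, dithering the quartile
        # quantization out of the window means.
        CovariateSpec(
            name="chl",
            units="mg m-3",
            constant=0.1,
            bumps=(bump,),
            seasonal_amplitude=0.25,
            seasonal_peak_doy=150.0,
            noise_sd=0.05,
            shiftable=True,
        ),
        CovariateSpec(name="o2", units="mmol m-3", constant=200.0, noise_sd=2.0),
        CovariateSpec(name="sla", units="m", constant=0.0, noise_sd=0.03),
        CovariateSpec(name="mld", units="m", constant=30.0, noise_sd=2.0),
    )
    return ScenarioConfig(
        grid=fine_grid,
        start_date="2010-08-01",
        end_date="2020-10-31",
        months=SEASON,
        covariates=covariates,
        suitability={"chl": 2.5},
        intercept=-4.0,
        events=(EventWindow(name="mhw_2015", start="2015-08-01", end="2015-10-31"),),
        shift=ShiftSpec(dlon=0.0, dlat=0.0, scale=scale),
        species=(TrackSpec("species_a", n_individuals=5, points_per_day=1),),
        seed=seed,
    )


def small_scenario(seed: int = 0) -> ScenarioConfig:
    """A fast miniature world for unit tests and determinism checks."""
    events = (
        EventWindow(
            name="mhw_2014",
            start="2014-08-01",
            end="2014-10-31",
            anomalies=(BoxAnomaly(covariate="sst", amplitude=2.0),),
        ),
    )
    return ScenarioConfig(
        grid=GridSpec(lon_min=-134.0, lon_max=-126.0, lat_min=33.0, lat_max=41.0, res=0.5),
        start_date="2012-08-01",
        end_date="2014-10-31",
        months=SEASON,
        covariates=_covariates(),
        suitability={"chl": 2.5, "sst": 0.25},
        intercept=-8.0,
        events=events,
        shift=ShiftSpec(dlon=-1.0, dlat=1.0, scale=1.0),
        species=(TrackSpec("species_a", n_individuals=4, points_per_day=1),),
        seed=seed,
    )
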