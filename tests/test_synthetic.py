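"""The synthetic world: recoverable anomalies, suitability-driven tracks,
tiling jurisdictions, and bit-level determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import mhw_habitat as mh
from mhw_habitat.grid import GridSpec
from mhw_habitat.synthetic import (
    BoxAnomaly,
    ConfigurationError,
    CovariateSpec,
    EventWindow,
    ScenarioConfig,
    ShiftSpec,
    TrackSpec,
)

GRID = GridSpec(-10.0, 0.0, 30.0, 40.0, 0.5)


def scenario(covariates, suitability, events=(), shift=ShiftSpec(), **kw):
    defaults = dict(
        grid=GRID,
        start_date="2015-06-01",
        end_date="2015-10-31",
        covariates=tuple(covariates),
        suitability=suitability,
        events=tuple(events),
        shift=shift,
        species=(TrackSpec("sp", n_individuals=2, points_per_day=2),),
        seed=5,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


EVENT = EventWindow(
    name="ev",
    start="2015-08-01",
    end="2015-10-31",
    anomalies=(BoxAnomaly(covariate="sst", amplitude=2.0, lon_min=-5.0, lat_max=35.0),),
)


class TestGenerateEnvironment:
    def test_zero_anomaly_zero_noise_is_pure_baseline(self):
        cov = CovariateSpec(name="sst", constant=15.0, lat_gradient=-0.5)
        sc = scenario([cov], {"sst": 1.0},
                      events=[EventWindow("ev", "2015-08-01", "2015-10-31")])
        env = mh.generate_environment(sc)
        field = env["sst"].values
        assert np.allclose(field, field[0])  # no seasonality, no anomaly, no noise

    def test_box_anomaly_exact_without_noise(self):
        cov = CovariateSpec(name="sst", constant=15.0)
        sc = scenario([cov], {"sst": 1.0}, events=[EVENT])
        env = mh.generate_environment(sc)
        t = pd.DatetimeIndex(env.time.values)
        in_ev = (t >= "2015-08-01") & (t <= "2015-10-31")
        diff = env["sst"].values[in_ev].mean(axis=0) - env["sst"].values[~in_ev].mean(axis=0)
        lon2d, lat2d = np.meshgrid(env.lon.values, env.lat.values)
        in_box = (lon2d >= -5.0) & (lat2d < 35.0)
        assert np.allclose(diff[in_box], 2.0)
        assert np.allclose(diff[~in_box], 0.0)

    def test_noisy_anomaly_recovered_within_clt_bound(self):
        cov = CovariateSpec(name="sst", constant=15.0, noise_sd=0.1)
        sc = scenario([cov], {"sst": 1.0}, events=[EVENT])
        env = mh.generate_environment(sc)
        t = pd.DatetimeIndex(env.time.values)
        in_ev = (t >= "2015-08-01") & (t <= "2015-10-31")
        assert int(in_ev.sum()) == 92
        diff = env["sst"].values[in_ev].mean(axis=0) - env["sst"].values[~in_ev].mean(axis=0)
        lon2d, lat2d = np.meshgrid(env.lon.values, env.lat.values)
        box_mean = diff[(lon2d >= -5.0) & (lat2d < 35.0)].mean()
        assert abs(box_mean - 2.0) < 3 * 0.1 / np.sqrt(92)

    def test_event_outside_range_rejected(self):
        cov = CovariateSpec(name="sst", constant=15.0)
        with pytest.raises(ConfigurationError, match="outside"):
            scenario([cov], {"sst": 1.0},
                     events=[EventWindow("ev", "2016-01-01", "2016-02-01")])

    def test_shiftable_bump_translates_during_event(self):
        from mhw_habitat.synthetic import GaussianBump

        bump = GaussianBump(amplitude=1.0, lon0=-5.0, lat0=35.0, sigma_lon=1.0, sigma_lat=1.0)
        cov = CovariateSpec(name="chl", bumps=(bump,), shiftable=True)
        sc = scenario([cov], {"chl": 1.0},
                      events=[EventWindow("ev", "2015-08-01", "2015-10-31")],
                      shift=ShiftSpec(dlon=-2.0, dlat=2.0))
        env = mh.generate_environment(sc)
        t = pd.DatetimeIndex(env.time.values)
        before = env["chl"].values[0]
        during = env["chl"].values[np.argmax(t >= pd.Timestamp("2015-08-01"))]
        ij_before = np.unravel_index(np.argmax(before), before.shape)
        ij_during = np.unravel_index(np.argmax(during), during.shape)
        assert env.lat.values[ij_during[0]] - env.lat.values[ij_before[0]] == pytest.approx(2.0, abs=0.5)
        assert env.lon.values[ij_during[1]] - env.lon.values[ij_before[1]] == pytest.approx(-2.0, abs=0.5)


class TestGenerateTelemetry:
    def test_uniform_suitability_gives_uniform_density(self):
        cov = CovariateSpec(name="x", constant=0.0)
        sc = scenario([cov], {"x": 0.0}, species=(TrackSpec("sp", 10, 5),))
        env = mh.generate_environment(sc)
        tel = mh.generate_telemetry(sc, env)
        ilat, ilon = GRID.point_to_cell(tel.lon.to_numpy(), tel.lat.to_numpy())
        counts = np.bincount(ilat * GRID.nlon + ilon, minlength=GRID.nlat * GRID.nlon)
        n, k = len(tel), GRID.nlat * GRID.nlon
        # chi-square-style sanity bound on the most extreme cell count
        assert counts.max() < n / k + 6 * np.sqrt(n / k)

    def test_zero_suitability_region_gets_no_presences(self):
        cov = CovariateSpec(name="x", constant=1.0, lon_gradient=1.0)
        # logistic weight -50 on x: suitability ~0 wherever x > 0 (east half)
        sc = scenario([cov], {"x": -50.0}, intercept=0.0)
        env = mh.generate_environment(sc)
        tel = mh.generate_telemetry(sc, env)
        assert (tel.lon < -5.0).all()

    def test_presence_counts_match_request(self, small_scenario, small_telemetry):
        per_species = small_telemetry.groupby("species").size()
        for sp in small_scenario.species:
            expected = sp.n_individuals * sp.points_per_day * len(small_scenario.dates)
            assert per_species[sp.species] == expected

    def test_presence_density_tracks_covariate(self):
        cov = CovariateSpec(name="x", constant=0.0, lon_gradient=0.3)
        sc = scenario([cov], {"x": 1.0}, species=(TrackSpec("sp", 10, 4),))
        env = mh.generate_environment(sc)
        tel = mh.generate_telemetry(sc, env)
        assert len(tel) >= 5000
        ilat, ilon = GRID.point_to_cell(tel.lon.to_numpy(), tel.lat.to_numpy())
        counts = np.bincount(ilat * GRID.nlon + ilon, minlength=GRID.nlat * GRID.nlon)
        x = env["x"].values[0].ravel()
        rho, _ = spearmanr(counts, x)
        assert rho > 0.5

    def test_all_zero_suitability_raises(self):
        cov = CovariateSpec(name="x", constant=100.0)
        sc = scenario([cov], {"x": -10.0}, intercept=0.0)
        env = mh.generate_environment(sc)
        with pytest.raises(ValueError, match="all-zero suitability"):
            mh.generate_telemetry(sc, env)


class TestJurisdictions:
    def test_zones_tile_domain(self, small_scenario, small_zones):
        g = small_scenario.grid
        domain_area = (g.lon_max - g.lon_min) * (g.lat_max - g.lat_min)
        total = sum(z.polygon.area for z in small_zones)
        assert total == pytest.approx(domain_area, rel=1e-9)

    def test_every_cell_in_exactly_one_zone(self, small_scenario, small_zones):
        zmap = mh.assign_cells(small_scenario.grid, small_zones)
        assert zmap.codes.size == small_scenario.grid.nlat * small_scenario.grid.nlon
        assert set(np.unique(zmap.codes)) <= set(range(len(zmap.zone_names)))

    def test_two_zone_split_assignment(self):
        cov = CovariateSpec(name="x", constant=0.0)
        sc = scenario([cov], {"x": 0.0})
        zones = mh.generate_jurisdictions(sc)
        zmap = mh.assign_cells(sc.grid, zones)
        # westernmost cell center is high seas; easternmost in a coastal band
        west = zmap.zone_names[zmap.codes[0, 0]]
        east = zmap.zone_names[zmap.codes[0, -1]]
        assert west == "high_seas"
        assert east.startswith("zone_")


class TestDeterminismAndIO:
    def test_same_seed_identical_outputs(self, small_scenario):
        env1 = mh.generate_environment(small_scenario)
        env2 = mh.generate_environment(small_scenario)
        for name in env1.data_vars:
            np.testing.assert_array_equal(env1[name].values, env2[name].values)
        tel1 = mh.generate_telemetry(small_scenario, env1)
        tel2 = mh.generate_telemetry(small_scenario, env2)
        pd.testing.assert_frame_equal(tel1, tel2)

    def test_different_seed_differs(self, small_scenario):
        env1 = mh.generate_environment(small_scenario)
        env2 = mh.generate_environment(replace(small_scenario, seed=small_scenario.seed + 1))
        assert not np.array_equal(env1["sst"].values, env2["sst"].values)

    def test_round_trips(self, tmp_path, small_scenario, small_env, small_telemetry, small_zones):
        from mhw_habitat import synthetic as syn

        syn.write_environment(small_env, tmp_path / "env.nc")
        env2 = syn.read_environment(tmp_path / "env.nc")
        np.testing.assert_allclose(small_env["sst"].values, env2["sst"].values)

        syn.write_telemetry(small_telemetry, tmp_path / "tel.csv")
        tel2 = syn.read_telemetry(tmp_path / "tel.csv")
        assert list(tel2.columns) == ["species", "individual", "date", "lon", "lat"]
        assert len(tel2) == len(small_telemetry)

        syn.write_jurisdictions(small_zones, tmp_path / "zones.geojson")
        zones2 = syn.read_jurisdictions(tmp_path / "zones.geojson")
        assert {z.name for z in zones2} == {z.name for z in small_zones}

    def test_config_yaml_round_trip(self, tmp_path, small_scenario):
        small_scenario.to_yaml(tmp_path / "scenario.yml")
        back = ScenarioConfig.from_yaml(tmp_path / "scenario.yml")
        assert back == small_scenario
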