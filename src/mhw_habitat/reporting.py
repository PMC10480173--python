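"""Ensemble uncertainty statistics, anomaly rasters, and the pipeline driver.

``run_pipeline`` executes the whole chain — simulate, build occurrences,
fit, predict, threshold, habitat metrics, jurisdictional accounting, and
replicate statistics — deterministically under one master seed.  Stage RNG
streams are derived from the master seed with a documented counter scheme
(``SeedSequence([master, stage_id])``; stage ids below), so any stage can
be re-run in isolation with the same stream.

Replicate statistics follow the usual ensemble-reporting conventions:
standard error is the sample (n-1) standard deviation over replicates
divided by sqrt(n), and the coefficient of variation is the sample SD over
the absolute mean, reported as missing (NaN) when the mean is zero.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import jurisdiction as juris
from . import occurrence as occ_mod
from . import synthetic
from .habitat_metrics import (
    binarize,
    compute_threshold,
    daily_stats,
    summaries_to_frame,
    summarize_event,
)
from .sdm import ModelConfig, fit_ensemble, fit_model, predict_daily
from .synthetic import ScenarioConfig

# Stage ids for the master-seed -> stage-seed derivation.
STAGE_ENVIRONMENT = 1
STAGE_TELEMETRY = 2
STAGE_PSEUDO_ABSENCE = 3
STAGE_MODEL = 4
STAGE_ENSEMBLE = 5
STAGE_KERNEL = 6

#: CSV float format used for every persisted table (fixed precision so
#: reruns are byte-identical).
FLOAT_FORMAT = "%.10g"


def stage_seed(master_seed: int, stage_id: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, stage_id]).generate_state(1)[0] % (2**31))


def replicate_stats(
    values: pd.DataFrame,
    group_cols: list[str],
    value_cols: list[str],
) -> pd.DataFrame:
    """Mean, standard error, and coefficient of variation across replicates.

    ``values`` holds one row per replicate per group.  Requires at least two
    replicates per group.  CV is NaN (not infinite) where the mean is zero.
    """
    out_rows = []
    for key, sub in values.groupby(group_cols, sort=True):
        if len(sub) < 2:
            raise ValueError(f"replicate statistics need >=2 replicates, got {len(sub)} for {key}")
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(sub)
        for col in value_cols:
            v = sub[col].to_numpy(dtype=float)
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1))
            row[f"{col}_mean"] = mean
            row[f"{col}_se"] = sd / np.sqrt(len(v))
            row[f"{col}_cv"] = sd / abs(mean) if mean != 0 else np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def anomaly_raster(
    cube: xr.DataArray,
    event_window: tuple[str, str],
    baseline_window: tuple[str, str],
) -> xr.DataArray:
    """Cellwise event-mean minus baseline-mean suitability; missing propagates."""
    t = pd.DatetimeIndex(cube["time"].values)
    ev = cube.sel(time=(t >= pd.Timestamp(event_window[0])) & (t <= pd.Timestamp(event_window[1])))
    bl = cube.sel(
        time=(t >= pd.Timestamp(baseline_window[0])) & (t <= pd.Timestamp(baseline_window[1]))
    )
    if ev.sizes["time"] == 0 or bl.sizes["time"] == 0:
        raise ValueError("event or baseline window not covered by the cube")
    out = ev.mean("time") - bl.mean("time")
    out.name = "suitability_anomaly"
    return out


@dataclass
class PipelineConfig:
    """Everything ``run_pipeline`` needs beyond the master seed."""

    scenario: ScenarioConfig
    model: ModelConfig = field(default_factory=ModelConfig)
    threshold_quantile: float = 0.5
    n_replicates: int = 20
    replicate_fraction: float = 0.75
    background_domain: str = "hull"
    baseline_window: tuple[str, str] | None = None  # default: full record

    def resolved_baseline(self) -> tuple[str, str]:
        if self.baseline_window is not None:
            return self.baseline_window
        return (self.scenario.start_date, self.scenario.end_date)


@dataclass
class PipelineResult:
    telemetry: pd.DataFrame
    occurrences: pd.DataFrame
    zones: list
    models: dict  # species -> SuitabilityModel
    thresholds: dict  # species -> float
    cubes: dict  # species -> suitability DataArray
    event_summaries: pd.DataFrame
    ledger: pd.DataFrame
    extremes: pd.DataFrame
    replicate_metric_stats: pd.DataFrame | None
    replicate_zone_stats: pd.DataFrame | None
    anomalies: dict  # (species, event) -> DataArray
    manifest: dict
    log: list


def _species_pipeline(
    occ_sp: pd.DataFrame,
    env: xr.Dataset,
    model_config: ModelConfig,
    threshold_quantile: float,
    events,
    baseline,
    zone_map,
    species: str,
):
    """Fit one model and take it through metrics + zonal accounting."""
    model = fit_model(occ_sp, model_config)
    cube = predict_daily(model, env)
    pres = occ_sp[occ_sp["label"] == 1]
    pres_scores = model.predict(pres[list(model.covariate_names)].to_numpy(dtype=float))
    thr = compute_threshold(pres_scores, threshold_quantile)
    core = binarize(cube, thr, species=species)
    stats = daily_stats(core)
    summaries = [
        summarize_event(stats, (ev.start, ev.end), baseline, species=species, event_name=ev.name)
        for ev in events
    ]
    zone_areas = juris.daily_zone_areas(core, zone_map)
    ledger = juris.zonal_ledger(
        zone_areas,
        [(ev.name, ev.start, ev.end) for ev in events],
        baseline,
        species=species,
    )
    return model, cube, thr, core, stats, summaries, ledger


def run_pipeline(
    config: PipelineConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full synthetic-world analysis deterministically.

    With ``out_dir`` set, writes all tabular artifacts as CSV (fixed float
    precision), the jurisdiction polygons as GeoJSON, per-event suitability
    anomalies as NetCDF, a line-delimited JSON log, and a manifest of
    outputs with their SHA-256 checksums.  Two runs with the same config
    and seed produce byte-identical files.
    """
    log: list[dict] = []

    def note(stage: str, **kw):
        entry = {"stage": stage, **kw}
        log.append(entry)

    scenario = replace(config.scenario, seed=seed)
    events = list(scenario.events)
    baseline = config.resolved_baseline()

    env = synthetic.generate_environment(scenario)
    note("simulate_environment", n_days=int(env.sizes["time"]),
         n_cells=int(env.sizes["lat"] * env.sizes["lon"]))
    telemetry = synthetic.generate_telemetry(scenario, env)
    note("simulate_telemetry", n_fixes=len(telemetry),
         species=sorted(telemetry["species"].unique().tolist()))
    zones = synthetic.generate_jurisdictions(scenario)
    zone_map = juris.assign_cells(scenario.grid, zones)
    note("assign_zones", zones=zone_map.zone_names,
         boundary_cells=zone_map.n_boundary_cells)

    labelled = occ_mod.sample_pseudo_absences(
        telemetry, scenario.grid, domain=config.background_domain,
        seed=stage_seed(seed, STAGE_PSEUDO_ABSENCE),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occurrences = occ_mod.match_covariates(labelled, env)
    note("occurrences", n_rows=len(occurrences),
         n_dropped=len(labelled) - len(occurrences))

    if not events:
        warnings.warn("no event windows configured: baseline-only statistics, "
                      "event summaries skipped", stacklevel=2)

    model_config = replace(config.model, seed=stage_seed(seed, STAGE_MODEL))
    models, thresholds, cubes, anomalies = {}, {}, {}, {}
    all_summaries, all_ledgers = [], []
    rep_metric_rows, rep_zone_rows = [], []
    for species in sorted(occurrences["species"].unique()):
        occ_sp = occurrences[occurrences["species"] == species].reset_index(drop=True)
        model, cube, thr, core, stats, summaries, ledger = _species_pipeline(
            occ_sp, env, model_config, config.threshold_quantile,
            events, baseline, zone_map, species,
        )
        models[species] = model
        thresholds[species] = thr
        cubes[species] = cube
        all_summaries.extend(summaries)
        all_ledgers.append(ledger)
        for ev in events:
            anomalies[(species, ev.name)] = anomaly_raster(cube, (ev.start, ev.end), baseline)
        note("species_model", species=species, threshold=thr,
             learning_rate=model.learning_rate, n_trees=model.n_trees)

        if config.n_replicates >= 2:
            ensemble = fit_ensemble(
                occ_sp, model_config,
                n_replicates=config.n_replicates,
                fraction=config.replicate_fraction,
                seed=stage_seed(seed, STAGE_ENSEMBLE),
            )
            for r, rep_model in enumerate(ensemble.models):
                _, rep_summaries, rep_ledger = _replicate_metrics(
                    rep_model, occ_sp, env, config.threshold_quantile,
                    events, baseline, zone_map, species,
                )
                for s in rep_summaries:
                    rep_metric_rows.append(
                        {
                            "species": species,
                            "event": s.event,
                            "replicate": r,
                            "displacement_km": s.displacement_km,
                            "bearing_deg": s.bearing_deg,
                            "extent_change_pct": s.extent_change_pct,
                            "area_change_pct": s.area_change_pct,
                        }
                    )
                rep_ledger = rep_ledger.assign(replicate=r)
                rep_zone_rows.append(rep_ledger)
            note("ensemble", species=species, n_replicates=config.n_replicates)

    event_summaries = summaries_to_frame(all_summaries)
    ledger = pd.concat(all_ledgers, ignore_index=True) if all_ledgers else pd.DataFrame()
    extremes = (
        juris.largest_shift_summary(ledger, [ev.name for ev in events])
        if events and not ledger.empty
        else pd.DataFrame()
    )

    rep_metric_stats = rep_zone_stats = None
    if rep_metric_rows:
        rep_metric_stats = replicate_stats(
            pd.DataFrame(rep_metric_rows),
            ["species", "event"],
            ["displacement_km", "bearing_deg", "extent_change_pct", "area_change_pct"],
        )
    if rep_zone_rows:
        rep_zone_stats = replicate_stats(
            pd.concat(rep_zone_rows, ignore_index=True),
            ["species", "event", "zone"],
            ["anomaly_pct"],
        )

    manifest = {
        "seed": seed,
        "stage_seeds": {
            "pseudo_absence": stage_seed(seed, STAGE_PSEUDO_ABSENCE),
            "model": stage_seed(seed, STAGE_MODEL),
            "ensemble": stage_seed(seed, STAGE_ENSEMBLE),
        },
        "covariate_selection": config.model.covariates
        if isinstance(config.model.covariates, str)
        else list(config.model.covariates),
        "threshold_quantile": config.threshold_quantile,
        "background_domain": config.background_domain,
        "baseline_window": list(baseline),
        "events": [[ev.name, ev.start, ev.end] for ev in events],
        "n_replicates": config.n_replicates,
        "thresholds": {sp: float(t) for sp, t in thresholds.items()},
    }

    result = PipelineResult(
        telemetry=telemetry,
        occurrences=occurrences,
        zones=zones,
        models=models,
        thresholds=thresholds,
        cubes=cubes,
        event_summaries=event_summaries,
        ledger=ledger,
        extremes=extremes,
        replicate_metric_stats=rep_metric_stats,
        replicate_zone_stats=rep_zone_stats,
        anomalies=anomalies,
        manifest=manifest,
        log=log,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _replicate_metrics(model, occ_sp, env, threshold_quantile, events, baseline, zone_map, species):
    cube = predict_daily(model, env)
    pres = occ_sp[occ_sp["label"] == 1]
    scores = model.predict(pres[list(model.covariate_names)].to_numpy(dtype=float))
    thr = compute_threshold(scores, threshold_quantile)
    core = binarize(cube, thr, species=species)
    stats = daily_stats(core)
    summaries = [
        summarize_event(stats, (ev.start, ev.end), baseline, species=species, event_name=ev.name)
        for ev in events
    ]
    zone_areas = juris.daily_zone_areas(core, zone_map)
    ledger = juris.zonal_ledger(
        zone_areas, [(ev.name, ev.start, ev.end) for ev in events], baseline, species=species
    )
    return stats, summaries, ledger


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}

    synthetic.write_telemetry(result.telemetry, out_dir / "telemetry.csv")
    files["telemetry"] = "telemetry.csv"
    occ_mod.write_occurrences(result.occurrences, out_dir / "occurrences.csv")
    files["occurrences"] = "occurrences.csv"
    synthetic.write_jurisdictions(result.zones, out_dir / "zones.geojson")
    files["zones"] = "zones.geojson"

    result.event_summaries.to_csv(
        out_dir / "event_summaries.csv", index=False, float_format=FLOAT_FORMAT
    )
    files["event_summaries"] = "event_summaries.csv"
    result.ledger.to_csv(out_dir / "jurisdiction_ledger.csv", index=False,
                         float_format=FLOAT_FORMAT)
    files["jurisdiction_ledger"] = "jurisdiction_ledger.csv"
    if not result.extremes.empty:
        result.extremes.to_csv(out_dir / "largest_shifts.csv", index=False,
                               float_format=FLOAT_FORMAT)
        files["largest_shifts"] = "largest_shifts.csv"
    if result.replicate_metric_stats is not None:
        result.replicate_metric_stats.to_csv(
            out_dir / "replicate_metric_stats.csv", index=False, float_format=FLOAT_FORMAT
        )
        files["replicate_metric_stats"] = "replicate_metric_stats.csv"
    if result.replicate_zone_stats is not None:
        result.replicate_zone_stats.to_csv(
            out_dir / "replicate_zone_stats.csv", index=False, float_format=FLOAT_FORMAT
        )
        files["replicate_zone_stats"] = "replicate_zone_stats.csv"

    imp = pd.concat(
        {sp: m.importance for sp, m in result.models.items()}, names=["species", "covariate"]
    ).rename("relative_importance").reset_index()
    imp.to_csv(out_dir / "variable_importance.csv", index=False, float_format=FLOAT_FORMAT)
    files["variable_importance"] = "variable_importance.csv"

    for (species, event), anom in result.anomalies.items():
        name = f"anomaly_{species}_{event}.nc"
        anom.to_netcdf(out_dir / name)
        files[f"anomaly/{species}/{event}"] = name

    with open(out_dir / "log.ndjson", "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    files["log"] = "log.ndjson"

    manifest = dict(result.manifest)
    manifest["files"] = {
        key: {"path": rel, "sha256": _sha256(out_dir / rel)} for key, rel in files.items()
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
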