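# mhw-habitat

Marine heatwaves — discrete periods of extreme ocean warmth — can push the
habitat of wide-ranging marine predators hundreds of kilometres in a single
season, across national maritime boundaries. `mhw-habitat` is a tested,
reusable implementation of the analysis chain that quantifies those impacts
from animal telemetry and gridded ocean data:

1. **Occurrences** — telemetry presences are paired 1:1 with same-date
   background pseudo-absences drawn from the species' convex hull, and both
   are matched in space and time to daily environmental covariates
   (temperature and its spatial SD, chlorophyll, oxygen, sea-level anomaly,
   mixed-layer depth, day of year) on a regular lat/lon grid.
2. **Suitability model** — a boosted regression tree (bernoulli loss, bag
   fraction 0.6, tree complexity 3, learning rate chosen from
   {1e-4, 1e-5} so that at least 2000 trees are fit) estimates
   P(presence | environment), predicted daily over the grid and masked to
   the minimum convex hull of the training data.
3. **Core habitat** — daily suitability is thresholded at the 50% quantile
   of predictions at true presences, giving daily binary core-habitat
   rasters.
4. **Impact metrics** — per event window (e.g. Aug–Oct of a heatwave year)
   relative to the Aug–Oct all-years climatology: displacement of the
   core-habitat center of gravity (haversine km + compass bearing),
   range-extent change (% change of the N–S x E–W interquartile-range
   product, degrees²), and habitat-area change (% change of km², with
   cos-latitude cell areas).
5. **Jurisdictional accounting** — daily core habitat is partitioned across
   EEZ-style polygons plus a residual high-seas zone; per-zone area
   anomalies, largest gains/losses, and replicate-ensemble mean/SE/CV
   (20 x 75%-subsample refits) are reported.

Because the original telemetry and ocean reanalyses are large and access
restricted, the package ships a first-class **synthetic-data generator**: a
configurable world with known species–environment relationships, injected
heatwave anomalies, and injected habitat translations/expansions, so every
stage of the pipeline is verifiable against ground truth.

## Worked example

```python
import mhw_habitat as mh
from mhw_habitat.reporting import PipelineConfig, run_pipeline
from mhw_habitat.sdm import ModelConfig

config = PipelineConfig(
    scenario=mh.default_scenario(),   # 11 seasons, 2 heatwaves, 2 species
    model=ModelConfig(),              # the production boosted-tree settings
    n_replicates=2,
)
result = run_pipeline(config, seed=1, out_dir="out")
print(result.event_summaries[["species", "event", "displacement_km",
                              "bearing_deg", "area_change_pct"]])
```

prints (abridged; the `ardenna_synthetica` rows):

```
           species    event  displacement_km  bearing_deg  area_change_pct
ardenna_synthetica mhw_2014       121.6        323.9           -10.8
ardenna_synthetica mhw_2015       121.6        323.9           -11.1
```

The scenario injects a one-degree northwest shift of the habitat-defining
chlorophyll patch during each heatwave: the pipeline recovers a ~122 km
displacement toward 324° (NW) against the event-inclusive climatology, with
a modest net habitat loss. The jurisdiction ledger for the same run shows
the habitat leaving the coastal zones for the high seas (e.g. `zone_a`
−99.9%, `high_seas` +19.5% in 2014).

The same stages are scriptable from a shell:

```sh
mhw-habitat simulate   --config scenario.yml --seed 1 --out-dir out
mhw-habitat occurrence --config scenario.yml --seed 1 --out-dir out
mhw-habitat fit        --seed 1 --out-dir out
mhw-habitat predict    --out-dir out --species species_a
mhw-habitat metrics    --config scenario.yml --out-dir out --species species_a
mhw-habitat zones      --config scenario.yml --out-dir out --species species_a
mhw-habitat run        --config scenario.yml --seed 1 --out-dir out   # everything
```

All outputs (CSV tables, GeoJSON polygons, NetCDF rasters, an ndjson log and
a checksummed manifest) are byte-reproducible from config + seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the showcase scenario end to end — simulation, pseudo-absences,
boosted-tree fits at the production settings, daily prediction,
core-habitat metrics, jurisdictional ledger, and replicate statistics —
prints the event summaries and ledger it computed, and writes the results
file. Everything derives from `--seed`; see `docs/methods.md` for what the
synthetic world does and does not establish.
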