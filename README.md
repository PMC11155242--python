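# bioscape

A landscape-scale biodiversity footprint pipeline on synthetic landscapes:

1. **synthetic_landscape** — seeded generation of every input: a categorical
   land-cover base map with autocorrelated patches, support layers
   (forest management, forest integrity, livestock density, potential
   natural vegetation, crop suitability, DEM), road polylines, department
   polygons, connected species ranges with elevation envelopes, and a
   subnational trade table with untraced volume.
2. **landuse_harmonizer** — priority-ordered allocation of the base map into
   nine land-use classes (cocoa first, then agriculture, greedy pasture
   fill against an area budget, forest classes from management + integrity,
   primary vegetation, built-up).
3. **msa_model** — mean species abundance in [0, 1] under three multiplicative
   pressures (land-use lookup, road-distance bands, patch-area fragmentation
   response) plus a precultivation counterfactual (cocoa cells replaced by
   primary forest) whose MSA difference is the cocoa intactness loss.
4. **biodiversity_importance** — per-species rarity-weighted richness
   (in-cell range area / global range area, elevation-filtered), cellwise
   aggregation, and the rarity index RI (log transform, mean-1
   normalization, floor at 0.05).
5. **impact_metrics** — suitability-weighted yield downscaling conserving
   national production; BIM_total = (1 − MSA)·RI·area; BIM_cocoa =
   MSA-loss·RI·area on cocoa cells; BF = BIM_cocoa per tonne; department
   aggregates with full-sun/agroforestry splits and relative shares.
6. **supplychain_attribution** — flow-level impact attribution (tonnes × BF),
   untraced-volume-weighted factors for UNKNOWN-origin flows, exporter /
   importer aggregation with exact impact conservation.

Rasters are single-band ESRI ASCII grids (`.asc`) with a JSON sidecar for
kind/CRS/legend; vectors are GeoJSON; tables are CSV; configs are YAML.
All layers in a run share one grid — mixed grids are refused, never
silently resampled.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance contract: conservation
properties (production, RWR mass, impact totals), MSA bounds and
monotonicity, greedy-vs-oracle pasture allocation, vectorized-vs-loop
equivalence, importer mixing convexity, the agroforestry/full-sun
directional sign pattern, and end-to-end bit-reproducibility at 256×256.

## CLI

```sh
bioscape run-all --config config.yaml --outdir out/ [--seed 7] [--resume]
bioscape synth|harmonize|msa|importance|impact|trade --config config.yaml --outdir out/
```

Stage subcommands run the pipeline up to the named stage, reusing cached
outputs of earlier stages in `outdir`. Exit codes: 0 success, 2 validation
error, 3 stage failure. A minimal config:

```yaml
seed: 7
grid: {n_rows: 128, n_cols: 128, cell_size: 100.0, origin_x: 0.0, origin_y: 12800.0}
ri_floor: 0.05
flii_threshold: 6.0
pasture_area_budget_ha: 2000
national_production_t: 2000000
occupation_years: 1
landscape: {cocoa_fraction: 0.15, n_roads: 6, n_departments: 12}
species: {n_species: 50}
trade: {n_exporters: 10, n_importers: 10, untraced_fraction: 0.544, export_fraction: 0.93}
```

The run summary (`out/summary.json`) records per-file checksums, national
BIM totals, the cocoa share of cocoa-area impacts, and the export share of
attributed impacts; identical config + seed reproduces identical checksums.

## MSA parameters

`MSAParams` ships documented defaults (land-use MSA table, road-distance
bands, fragmentation breakpoints) that can be overridden from YAML via the
`msa_params_path` config key; `MSAParams.to_yaml` writes a template.
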