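# esmap

National-scale land-cover change accounting and matrix-based mapping of
ecosystem-service (ES) supply potential, with a synthetic-landscape
generator so the entire pipeline is testable offline.

The pipeline takes a multi-year series of categorical land-cover rasters
(GeoTIFF, integer class codes, one per year), nested administrative zones
(GeoJSON) and a services × land-cover score matrix (CSV, scores 0–5 with
min/avg/max variants), and produces:

- **Extent accounts** — per-class areas (km²), year-to-year class
  transition matrices, and net/percent change tables relative to a
  baseline year, at national / regional / sub-regional level.
- **ES supply maps** — one score raster per (service, variant, year) by
  lookup reclassification, plus equal-weight aggregate maps (raw sum and
  min–max standardized).
- **Zonal summaries** — area-weighted mean score per unit area and
  score·km² totals per zone/service/year, changes vs. the baseline, and
  service rankings.
- **Synthetic data** — Voronoi-patch landscapes with configurable class
  proportions, Markov-chain year-to-year change with known ground truth,
  rectangular nested zones, and literature-style study matrices.

## CLI

```bash
# 1. generate a synthetic 2-year scenario (or bring your own GeoTIFFs)
esmap simulate --seed 1 --size 500 --out data/sim
# optionally: esmap simulate --scenario scenario.yaml --out data/sim

# 2. change accounts (areas, transitions, percent change vs. baseline)
esmap change --rasters "data/sim/lc_*.tif" --baseline 2015 \
    --zones data/sim/zones.geojson --area-mode nominal --out out/change

# 3. ES scoring and aggregation (matrix.csv in long format:
#    service_code,service_name,class_code,variant,score,n_studies)
esmap score --rasters "data/sim/lc_*.tif" --matrix data/sim/matrix.csv \
    --variants avg,max --zones data/sim/zones.geojson --out out/score

# 4. service rankings from the zonal summary
esmap report --summary out/score --out out/rankings.csv
```

Exit codes: 0 success, 1 usage/config error, 2 data validation error,
3 internal error. `--area-mode geodesic` (default for geographic CRS)
computes per-row spherical pixel areas; `nominal` uses a constant pixel
area (default 0.01 km², i.e. 100 m pixels).

An illustrative 10-service × 11-class score matrix ships at
`src/esmap/data/example_matrix.csv`. **Its numbers are plausible
placeholders for demos only** — for real assessments supply a matrix
transcribed from a literature review (the packaged tests never rely on
these values).

## Package layout

| module | contents |
| --- | --- |
| `esmap.geodata_io` | `Grid`, `Legend`, `LandCoverRaster`, `ZoneSet`, `PixelAreaField`; GeoTIFF/GeoJSON/CSV I/O, clipping, series validation, pixel areas |
| `esmap.change_accounts` | class areas, `TransitionMatrix`, net change, change tables, CSV writers |
| `esmap.es_scoring` | service registry, study matrices, crosswalks, consensus `ESMatrix`, score rasters |
| `esmap.aggregation_reporting` | equal-weight aggregation, zonal means/totals, change summaries, rankings |
| `esmap.synthetic_data` | landscape/zones/study generators, Markov transitions, scenario YAML |
| `esmap.cli` | `esmap simulate / change / score / report` |
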