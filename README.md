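# phenorisk

Spatialized insect phenology and climatic-suitability risk modeling on
daily temperature grids, with packaged defaults for emerald ash borer
(*Agrilus planipennis*).

The model couples two daily accumulations over a calendar year:

- **Phenology** — a cohort-structured life-cycle simulation driven by
  single-triangle degree-days (lower threshold with a horizontal upper
  cutoff). Within-population variation in overwintering (J-larval)
  development is a truncated lognormal split into weighted cohorts; each
  cohort advances overwintered larva → pupa → adult → egg → larva, and
  five phenological events (pupation, adult emergence, oviposition, egg
  hatch, J-larval formation) are mapped as days of year, per cohort and
  cohort-combined.
- **Climatic suitability** — cold and heat stress units (degree-days
  below −31 °C / above 38 °C for the default parameterization) accumulate
  daily; yearly totals classify each cell as not excluded (0), moderately
  excluded (−1), or severely excluded (−2). Class-0 cells form the
  potential distribution, and phenology maps are masked accordingly.

The package also ships the associated evaluation tooling: error summaries
(MAE, bias, SD, range), Welch-based TOST equivalence tests, per-pixel
Mann-Kendall trend tests, multi-year agreement maps, presence-record
sensitivity, and a synthetic-weather generator so everything runs without
external climate downloads.

## CLI

```sh
# generate a year of synthetic daily Tmin/Tmax (NetCDF)
phenorisk synth-weather --rows 20 --cols 20 --noise-sd 2 --seed 1 --out weather.nc

# full model run (GeoTIFF rasters + PNG maps + provenance JSON)
phenorisk run --weather weather.nc --out-dir out/
phenorisk run --synthetic --rows 20 --cols 20 --seed 1 --out-dir out/

# compare predictions to observed event dates (MAE/bias + TOST at ±7/±14 d)
phenorisk validate --run-dir out/ --observations obs.csv --out report.json

# per-pixel Mann-Kendall trends across yearly runs
phenorisk trend --run-dirs y2002/ --run-dirs y2003/ ... --variable first_emergence_doy --out-dir trends/

# grid-search cohort-distribution parameters against emergence observations
phenorisk calibrate-cohorts --observations obs.csv --weather-dir sites/ \
    --candidates grid.csv --out ranked.json
```

Observation CSVs for `validate` need columns
`event,site,year,lon,lat,observed_doy` with event names from
`pupation, adult_emergence, oviposition, egg_hatch, jlarval_formation`.

Species parameters are plain `key = value` files (see
`src/phenorisk/data/eab.params`); keys omitted in a user file fall back to
the packaged defaults.

## Layout

| module                  | responsibility                                      |
|-------------------------|-----------------------------------------------------|
| `phenorisk.params`      | parameter file schema, parsing, validation          |
| `phenorisk.weather`     | Tmin/Tmax grid container, synthesis, I/O, extraction|
| `phenorisk.degree_days` | single-triangle degree-day and stress kernels       |
| `phenorisk.cohorts`     | cohort construction and calibration grid search     |
| `phenorisk.phenology`   | daily life-cycle engine, event maps, snapshots      |
| `phenorisk.suitability` | stress accumulation, exclusion classes, integration |
| `phenorisk.stats`       | error summaries, TOST equivalence                   |
| `phenorisk.trends`      | Mann-Kendall tests, scalar and per-pixel            |
| `phenorisk.cli`         | `run` / `validate` / `trend` / `synth-weather` / `calibrate-cohorts` |
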