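# indoorclim

Workplace-specific indoor climate projections. The package trains small
neural surrogates that map outdoor weather to indoor air temperature
(`ti`) and indoor physiologically equivalent temperature (`pet`),
bias-corrects climate-scenario inputs by quantile delta mapping against a
historical reference, and computes heat-stress exposure statistics
(exceedance hours, heat days, consecutive-run durations, stress-class
frequencies) for a historical and a future period. A synthetic-data
module emulates outdoor reanalysis series, scenario ensemble members with
known imposed change, and indoor sensor records from a parameterized
building response, so the full pipeline runs and is testable offline with
known ground truth.

## Modules

| module | purpose |
| --- | --- |
| `indoorclim.series` | `MeteoSeries` / `IndoorSeries` containers, CSV I/O, physical invariants |
| `indoorclim.synthetic` | outdoor weather generator, scenario perturbations, single-node indoor simulator |
| `indoorclim.memi` | two-node human heat-balance model and the PET reference search |
| `indoorclim.comfort` | vapor pressure, globe-to-mean-radiant conversion, PET, stress classes |
| `indoorclim.surrogate` | 18-feature lag matrix, 80/10/10 split, 18-16-1 sigmoid MLP (Adam, early stopping) |
| `indoorclim.qdm` | quantile delta mapping per variable (additive / multiplicative with trace rule) |
| `indoorclim.metrics` | noleap normalization, exceedance hours (x3 rule), heat days, runs, stratified frequencies |
| `indoorclim.pipeline` | end-to-end experiment, ensemble aggregation, period deltas |
| `indoorclim.cli` | `indoorclim` command with `simulate`, `pet`, `train`, `bias-correct`, `project` |

## CLI

```sh
# synthetic outdoor + indoor year
indoorclim simulate --seed 3 --years 1 --outdoor-out outdoor.csv --indoor-out indoor.csv

# fill the PET column of an indoor series
indoorclim pet indoor.csv --out indoor_pet.csv

# train one surrogate (target ti or pet)
indoorclim train --outdoor outdoor.csv --indoor indoor_pet.csv --target ti \
    --seed 1 --model-out model.json --log-out losses.csv

# QDM-correct a scenario member
indoorclim bias-correct --obs-hist obs.csv --mod-hist hist.csv --mod-fut fut.csv \
    --out corrected.csv --log-out repairs.json

# full experiment from YAML
indoorclim project experiment.yaml --report-out report.json --tidy-out metrics.csv
```

An experiment YAML has two top-level keys, `workplace` (fields of
`pipeline.WorkplaceConfig`; nested `building`, `climate`, `person`,
`historical`, `future`, `hyper` mappings) and `scenarios` (a list of
`synthetic.ScenarioConfig` fields). See `tests/test_cli.py` for a
complete example.

### File schemas

Series CSVs have an ISO-8601 UTC `timestamp` column plus one column per
variable (`ta td v p g ag` outdoor; `ti rh tg vi pet` indoor). Models are
a single JSON file (architecture, weights, scalers, metadata). Projection
reports are JSON (historical metrics, per-member metrics, ensemble
mean/median/range, deltas with percent changes) plus an optional tidy CSV
with one row per period x metric x threshold x stratum.

## Conventions worth knowing

- PET uses the standardized reference person (male, 35 y, 1.75 m, 75 kg,
  0.9 clo, 80 W activity) and the reference environment t_mrt = t_a,
  v = 0.1 m/s, VP = 12 hPa; air speed is floored at 0.1 m/s.
- Stress classes: cold (PET <= 18), comfortable (open interval 18-23),
  then slight / moderate / strong / extreme heat at >= 23 / 29 / 35 / 41.
- Exceedance thresholds are inclusive: ti >= 26 / 30 / 35, pet >= 23 /
  29 / 35 / 41; at 3-h resolution each exceeding step counts 3 hours.
- Working hours are the closed interval 09:00-18:00 UTC (4 of 8 daily
  steps at 3-h resolution).
- All projections are normalized to a noleap calendar (Feb 29 removed)
  before metrics.
- QDM defaults: additive for ta, td, p, ag; multiplicative with trace
  0.05 for g and v; pooled fitting (monthly grouping available).
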