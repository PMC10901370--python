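# cleans

Nitrogen lost from cropland to rivers, lakes and groundwater — through
soil erosion, surface runoff and leaching — spikes during **extremely
wet years** (EWYs). The mechanism is a two-year one: in a dry year
crops lose little nitrogen to water and leave a large residual mineral-N
pool in the soil; if the next year is very wet, that stored nitrogen is
flushed out together with the fresh application, producing a loss pulse
far above the long-term average.

`cleans` is a Python package for studying this phenomenon end to end on
a synthetic agroecosystem, and for evaluating the **CLEANS** strategy
(Climate Extreme Adaptive Nitrogen Strategy): *scale nitrogen input down
by a fixed ratio only in years whose consecutive-year precipitation
difference exceeds a threshold*, choosing the (threshold, ratio) pair
per region and crop to maximize the reduction of extreme losses under
caps on yield loss and input reduction. It is aimed at
agro-environmental modellers who want a transparent, fully seeded
sandbox in which every statistic of the analysis chain is testable
against a known ground truth.

## The statistics at the core

For each food production unit (FPU) *i* with annual precipitation
`aPr_{i,t}`, baseline mean `m_i` and SD `s_i`:

* **standardized anomaly** `SA_{i,t} = (aPr_{i,t} − m_i) / s_i`; a year
  is an EWY when `SA > 2`;
* **extreme N_w**: the mean aquatic N loss over EWY years expressed as a
  relative change (%) from the unit's long-term mean loss (0 for units
  without EWYs);
* **diffPr** `= (aPr_{i,t} − aPr_{i,t−1}) / m_i`, the wet-after-dry
  indicator that turns out to be the dominant driver of extreme losses;
* a **random-forest surrogate** per crop (predictors: annual climate,
  diffPr, N input, soils, irrigation and EWY indicators) trained on the
  emulator output with an 80/20 split and 10-fold CV over
  `mtry`/`ntree`;
* the **CLEANS optimizer**: exhaustive scan of a threshold × ratio grid,
  feasible = {yield loss < 3 %, input reduction < 15 %} (strict),
  maximizing the extreme-loss reduction.

The process model behind the numbers is an annual soil nitrogen-balance
emulator with residual-N carryover and a logistic wetness-driven loss
fraction; see `docs/methods.md`.

## Worked example

```python
from cleans import RunConfig, run_pipeline

cfg = RunConfig()                 # 200 FPUs, 3 crops, 30 years
cfg.world.n_fpus = 60             # keep the example quick
cfg.crops = ("maize",)
run_pipeline(cfg, outdir="run")
```

This writes `world.csv`, `records.csv`, `anomalies.csv`,
`extremes.csv`, `intervals.csv`, `drivers.csv`, `cleans.csv` (among
others) plus `manifest.json` under `run/`. On this configuration the
manifest reports

```
"anomalies": { "ewy_frequency_pct": 2.87, "rows": 1740 },
"extremes":  { "area_weighted_extreme_nw_pct": 88.27, "units_with_ewy": 40, "units": 58 },
"cleans":    { "units": 58, "feasible": 58 }
```

— 58 of the 60 generated units survive the smallest-area exclusion;
fewer than 3 % of unit-years are extremely wet, yet in those years the
aquatic loss of an average (area-weighted) unit nearly doubles (+88 %
relative to its long-term mean). `cleans.csv` then holds, per unit,
the optimal (threshold, ratio) pair and its effects; on this run the
area-weighted mean change of extreme loss across feasible units is
−25.7 % at an area-weighted yield change of −1.5 % (the suite asserts
these as sign/threshold properties, not exact figures).

The same stages are available from the shell:

```sh
cleans run-all --config cfg.yaml --out run
cleans anomalies --config cfg.yaml --out run   # stop after a stage
```

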