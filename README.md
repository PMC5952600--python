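# coreud

Utilization distributions, quantitative core-space delineation and
movement-model imputation for satellite telemetry of central-place foragers
(pinnipeds hauling out on coastal sites, and similar systems).

Biologists tracking animals with Argos-class tags face a chain of standard
problems before they can say anything about space use: fixes arrive at
irregular times with class-dependent errors of 0.15–3 km, tracks contain
unusable locations and multi-day gaps, and naive kernel density estimates on
raw fixes confound sampling effort with behaviour. This package implements
that chain as a tested pipeline:

1. **Filtering** — drop fixes with no accuracy estimate (LC Z), apply a
   forward-pass swim-speed filter (≤ 8 m/s), truncate tracks at the first
   gap > 4 days.
2. **Movement model** — fit a continuous-time correlated random walk (CTCRW;
   Ornstein–Uhlenbeck velocity `dv = −βv dt + σ dW`, position integrating
   velocity, observed with LC-class Gaussian error) by maximum likelihood
   through a Kalman filter over the irregular fix times; impute
   pseudolocations every 2 h (12/day) as the average of 500 draws from the
   smoothing distribution; move on-land pseudolocations to the nearest water
   cell.
3. **Utilization distributions** — Gaussian-kernel density on a 1 km × 1 km
   grid with a likelihood cross-validation bandwidth, per animal and
   bi-monthly season (eligible when > 50 pseudolocations and
   pseudo-to-raw ratio < 3), plus an effort-corrected pooled UD weighting
   each cell by the fraction of animals observed in it.
4. **Home range and core** — 95% volume isopleth, land-clipped, as the home
   range; core boundary `v*` from an exponential regression
   `A(v) = a·e^{bv/100}` of normalized UD area on isopleth volume, solved
   where the slope equals 1 (`v* = 100·ln(1/(ab))/b`); intensity-of-use
   index `I = v* / (core area as % of home range)`, with `I < 1` meaning no
   distinguishable core.
5. **Model selection** — Akaike weights, the ΔAIC < 6 non-nested final-model
   set, and relative importance as the sum of weights of models containing a
   term, over candidate summaries from any fitting backend (a minimal OLS
   backend is included).

A seeded synthetic-data module generates coastline landscapes, haulout
sites, and duty-cycled Argos-like tracks with all of the artifacts above, so
the entire pipeline is testable without field data.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(8 animals, 3 haulouts, 120-day deployments) into `results/`:

```sh
python analysis/01_simulate_tracks.py --seed 1
python analysis/02_preprocess_fixes.py
python analysis/03_impute_tracks.py --seed 1
python analysis/04_estimate_uds.py
python analysis/05_range_core_metrics.py
python analysis/06_model_selection.py
```

With seed 1 the cleaning stage reports

```
input fixes:        8461
LC Z removed        243  (2.9%)
speed filtered      0  (0.0%)
gap truncated       697  (8.2%)
kept 7521 fixes across 8 animals
```

and the metrics stage summarises 16 eligible bi-monthly UDs:

```
hr_area_km2                  mean    150.29  min    59.25  max    286.65
core_area_km2                mean     26.41  min    11.25  max    44.12
isopleth_volume_core_pct     mean     79.13  min    73.25  max    83.05
proportion_core_pct          mean     18.54  min    13.68  max    25.04
intensity_I                  mean      4.40  min     2.94  max     5.91
min_dist_core_haulout_km     mean      1.59  min     1.08  max     2.41
```

Every animal shows a genuine core (`I` well above 1) whose polygons sit
within ~2 km of a haulout — the expected signature of strongly
haulout-anchored movement. The model-selection script is a negative control:
the generator encodes no sex or season effect, and the final model set
correctly collapses to the intercept-only model with zero importance for
both predictors.

## Layout

```
src/coreud/          simulate, preprocess, ctcrw, ud, range_core, modelsel,
                     pipeline, io
analysis/            numbered narrative drivers (simulate → model selection)
tests/               pytest suite, including acceptance properties
docs/methods.md      models, parameters, numerical choices, limitations
```
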