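# dryspell

Stem growth and canopy greenness respond differently when conifer forests
hit a dry summer: the ring laid down that year is narrower (often for
several years afterwards — the drought *legacy*), while canopy greenness
as seen from satellite (NDVI) dips and may rebound or keep sagging.
`dryspell` implements the full analysis chain used to quantify those
responses for two temperate conifers (*Picea abies* — PCAB, *Pinus
sylvestris* — PISY) sampled on plots spread over four topographic
categories (south slope, north slope, plateau, valley), together with a
synthetic-data generator that emulates the whole study design so every
stage can be exercised and tested without any download.

The pipeline, stage by stage:

- **Tree rings.** Each tree's ring-width series is detrended with a
  30-year cubic smoothing spline with a 50% frequency cutoff; the
  tree-ring index is TRI(t) = w(t) / ŵ(t). Plot chronologies are the
  per-year Tukey biweight robust mean of the tree indices.
- **Canopy greenness.** Per-scene NDVI = (NIR − Red)/(NIR + Red) from
  red/NIR reflectance with cloud masks; scenes are subset to a thermal
  growing season (start: first day whose five preceding days average
  above 12 °C for PISY, 9 °C for PCAB; end: 30 September), composited to
  per-pixel annual medians, averaged over pixels with plot-overlap
  weights, and linearly detrended to residuals.
- **Drought indexing.** Thornthwaite potential evapotranspiration,
  SPEI at the 4-month scale (log-logistic fit by unbiased
  probability-weighted moments), seasonal means (JJA, May–September),
  standardized JJA solar-radiation severities, and greedy selection of
  the four most severe non-consecutive drought years.
- **Superposed epoch analysis.** Mean departures of TRI / NDVI residuals
  at lags −4..+4 around the events, with significance from 1000 random
  non-consecutive event sets.
- **Response models.** Random-intercept linear mixed models (REML) of the
  response at lags 0..4 on the event-year severity SEV0 and the row-year
  severity SEV, with plot category as the random effect; reported with
  AIC, marginal/conditional R² (Nakagawa), pseudo-R², t-values, VIF, and
  a ranova-style likelihood-ratio test of the random effect. Lloret-type
  resistance / recovery / resilience ratios complete the picture.

## Worked example

The numbered scripts under `analysis/` run the chain on the bundled
synthetic study design (33 years, 2 species × 20 plots, drought summers
injected in 1994, 2003, 2006 and 2015):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_chronologies.py
python analysis/03_greenness.py
python analysis/04_climate_indices.py
python analysis/05_epoch_analysis.py
python analysis/06_response_models.py
```

which prints, among other things:

```
40 chronologies, 1985-2017
mean index 0.998 (expected ~1), mean interannual SD 0.126
mean index in the injected drought years: 0.707
...
selected drought years (highest JJA SR, non-consecutive): 1994 (z=1.67), 2003 (z=1.91), 2006 (z=2.15), 2015 (z=2.39)
...
TRI: lag-0 departure -0.288 (significant at p<0.05 in 40/40 plots)
NDVI: lag-0 departure -0.050 (significant at p<0.05 in 40/40 plots)
```

Reading this: chronologies are correctly centred near 1; in the injected
drought years mean TRI drops to ≈0.71 (the configured 20% growth drop
compounded with the high-radiation/low-moisture summer coupling); the
event-selection stage recovers exactly the four injected years from the
seasonal climate alone; and the epoch analysis sees a significant lag-0
decline in every plot for both compartments, with the NDVI dip matching
the configured 0.05. The model table printed by script 06 mirrors the
structure of the study's headline table (three variants per species ×
compartment, with AIC, R², t-values, VIF and the random-effect p).

The same chain runs as one command through the CLI:

```sh
dryspell run --seed 1 --out results/pipeline
```

## Layout

```
src/dryspell/      library: config, synthetic, tree_ring, greenness,
                   climate, epoch, models, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    model and design notes
```
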