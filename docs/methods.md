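# Methods notes

These notes record the models implemented in `dryspell`, the defaults and
why they were chosen, and the places where the design was genuinely open.

## Ring-width detrending

Tree-ring series are detrended with a cubic smoothing spline (scipy's
`make_smoothing_spline`, which minimizes Σ(wᵢ − f(tᵢ))² + λ∫f″²). For
unit-spaced data the amplitude frequency response of the fitted curve is
≈ 1/(1 + λω⁴), so a 50% response at wavelength P years needs
λ = (P/2π)⁴; with the default P = 30 this gives λ ≈ 519.7, and the
measured attenuation on a 330-year sinusoid is 50.02% — inside the ±1
point band the tests require, so no numerical re-tuning of λ is applied.
TRI = width / fitted, the ratio convention that keeps the index
dimensionless with mean ≈ 1.

Consequences worth knowing:

- The spline reproduces *linear* trends exactly (they are in the penalty
  null space), so a linear age trend detrends to TRI ≡ 1 to machine
  precision. A negative-exponential age curve has curvature, and over a
  33-year window the smoothing bias leaves TRI within ≈5·10⁻³ of 1 —
  small against the interannual signal but not zero.
- The fitted curve also tracks a small share of the *event* signal
  (broadband, mostly high-frequency), so injected departures at legacy
  lags are very slightly shallower after detrending than the raw
  injected fractions. Recovery tests therefore compare the noisy
  ensemble against the deterministic noise-free limit of the same chain
  rather than against the unfiltered injection arithmetic.

Missing rings are carried as NaN, excluded from the spline fit and from
averaging; a fitted value ≤ 0 raises rather than producing negative
indices. Series shorter than half the cutoff wavelength are rejected.

Chronologies use the Tukey biweight robust mean with tuning constant
9 × MAD, iterated from the median (≤10 iterations or relative change
< 10⁻⁶; median fallback when MAD = 0), and require a minimum sample
depth of 5 trees per retained year.

## Growing-season NDVI

NDVI is computed per scene first and composited afterwards (median of
scene NDVIs, not NDVI of median reflectances). The growing season starts
on the first day whose five *preceding* days (strict inequality,
current day excluded) average above the species threshold — 12 °C for
PISY, 9 °C for PCAB — and ends on the calendar date 30 September
(DOY 273 in common years, 274 in leap years; the calendar date is taken
as authoritative). Even-count medians average the two middle values.
Plot values are overlap-weighted pixel means with weights renormalized
over non-missing pixels; a year with no usable pixel is missing, not
zero. The long-term trend (canopy densification, CO₂ fertilization) is
removed by OLS of the annual value on calendar year, per plot; residuals
are the analysis variable.

## Drought indices

PET follows the classical Thornthwaite formulation: per-year heat index
I = Σ(Tₘ/5)^1.514 over warm months, exponent a(I), PET = 0 for T ≤ 0,
the Willmott polynomial above 26.5 °C, and day-length (latitude) and
month-length corrections.

SPEI accumulates D = P − PET over a k-month window *ending in and
including* the current month (k = 4 by default; the standard convention
for a "4-month" scale). For each calendar month a three-parameter
log-logistic is fitted over the calibration years (the full 1985–2017
analysis window by default) by unbiased probability-weighted moments
w_s = E[X(1−F)^s]. The fit uses the Hosking generalized-logistic
parametrization (κ = −τ₃), which is the log-logistic for κ < 0 and stays
well defined when a month's accumulated balance is left-skewed; values
outside the fitted support clamp to CDF 10⁻⁶ / 1−10⁻⁶. The
standard-normal quantile uses `scipy.stats.norm.ppf` (machine precision)
rather than a rational approximation.

Severities are standardized anomalies (baseline mean subtracted, divided
by baseline SD) so that solar radiation in J/m² yields interpretable
regression coefficients; raw-unit anomalies are available by flag.
Drought years are chosen greedily: repeatedly take the most extreme
remaining year whose neighbours (±1 year) are unselected, ties broken
toward the earlier year. The greedy rule is not guaranteed to maximize
total severity over all non-consecutive subsets, but coincides with the
exhaustive optimum on well-separated extremes (tested against brute
force).

## Superposed epoch analysis

Departures are relative to the overall series mean (the common SEA
convention). Events whose full ±lag window leaves the series support are
dropped with a warning — with a 4-year lag on a 1985–2017 series this
excludes a 2015 event, which is the honest consequence of requiring the
full window. The null resamples event sets of the same size, uniformly
without replacement from all years whose windows fit, preserving the
non-consecutiveness constraint of the real events (configurable).
P-values use the add-one permutation form (1 + #{|null| ≥ |obs|}) /
(1 + R), which floors p at 1/(R+1); R = 1000 by default. Significance is
read at two-sided α = 0.05.

## Mixed-effects response models

The response table stacks each plot's value in the event year and the
four following years (lags 0..4) against SEV0 (event-year severity,
constant within an event) and SEV (row-year severity; equal to SEV0 at
lag 0 by convention — the alternative SEV = 0 at lag 0 is available by
flag). NDVI residuals are standardized per plot (mean 0, SD 1) before
stacking so both compartments are on comparable scales; "scaled NDVI"
has no firmer published definition, and the z-form is the natural one.

The model is a Gaussian random-intercept LMM with the plot category as
the grouping factor, estimated by REML profiled to one dimension: for a
fixed variance ratio λ = σ²_group/σ²_resid the GLS fixed effects and the
residual variance are closed-form (the grouped covariance inverts by
Sherman–Morrison), and the profiled criterion is maximized over log₁₀λ
with a bounded scalar optimizer, checking the λ = 0 boundary explicitly
(reported as a singular fit, and collapsing exactly to OLS).
`statsmodels.MixedLM` serves as an independent cross-check in the test
suite, never as the implementation. A caveat that the tests encode: on
data whose *population* group variance is zero, REML still estimates a
small positive variance for roughly half the realizations — the exact
OLS collapse is guaranteed only when the *in-sample* group variance is
zero (errors centred within groups), and that is what the collapse tests
construct.

Reported per variant (full, without SEV0, without SEV):

- AIC = −2·REML-loglik + 2k with k = fixed effects + 2 variance
  parameters;
- marginal R² = var(Xβ̂)/(var(Xβ̂) + σ²_group + σ²_resid) and conditional
  R² with σ²_group added to the numerator (Nakagawa);
- pseudo-R² = squared Pearson correlation of observed and fitted values
  including group effects (the published analysis does not pin down its
  definition; this is the common one);
- VIF = 1/(1 − R²) from regressing each predictor on the rest (with
  intercept); perfect collinearity reports +inf;
- the random-effect test: 2·(REML loglik with the intercept − without),
  referred to χ²(1) with the statistic floored at 0. The fixed-only REML
  log-likelihood is computed on the same criterion as the mixed fit
  (the λ = 0 formula), so the two are directly comparable. χ²(1) rather
  than a 50:50 boundary mixture matches the cited reference behaviour
  and is the conservative choice.
- residual normality summarized as the correlation of sample vs
  theoretical normal quantiles (a numerical stand-in for a visual
  qq check).

Fixed-effect p-values are large-sample normal; no Satterthwaite or
Kenward–Roger correction (out of scope).

Resilience metrics are the Lloret ratios with 3-year pre/post windows
(the common convention): resistance = event/pre-mean, recovery =
post-mean/event, resilience = post-mean/pre-mean ≡ resistance × recovery.
Other event years are excluded from the windows.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed once to the study design: years 1985–2017, four
categories × 5 plots × 2 species, 26 trees per plot, drought years
{1994, 2003, 2006, 2015}.

- **Climate.** Daily temperature is a sinusoidal annual cycle with AR(1)
  weather noise (monthly T is the exact mean of daily T); monthly P, SR,
  SM have seasonal cycles with Gaussian noise at magnitudes typical of
  Central-European lowland/midland sites. Drought summers are *injected*:
  JJA SR is raised at least `sr_anomaly` (default 2.5) baseline SDs
  above the non-event mean — and above the highest background year, so
  the events really are the most extreme summers of the record, which is
  what the study's event definition ("the driest years") presumes — with
  an additional 0.35 SD spacing between events so that event-year
  severity is a non-degenerate regressor. JJA SM is depressed
  symmetrically.
- **Rings.** width = (A·e^(−age/τ) + c) × (1 + b_SR·z_SR + b_SM·z_SM) ×
  event multiplier × lognormal AR(1) noise. The negative-exponential age
  curve (A = 2 mm, τ = 80 yr, c = 0.5 mm) is the standard removable
  growth trend; lognormal noise keeps widths strictly positive. Event
  multipliers: 1 − growth_drop (0.2) at lag 0 and 1 − legacy_k at lags
  1..4 (defaults 0.10, 0.05, 0.02, 0.01), compounding across overlapping
  events. Tree ages start at 60–120 years, matching mature canopy trees.
- **Scenes.** Per plot a 2×2 pixel block with overlap weights
  (0.4/0.3/0.2/0.1 by default) stands in for the 16 m plot vs 30 m pixel
  geometry; geometry itself is not simulated. The pixel NDVI signal is a
  species base level (0.70 PCAB / 0.62 PISY) + linear trend
  (+0.002 yr⁻¹) + a mild seasonal hump + event effects (−0.05 at lag 0,
  +0.02 at lags 1–2) + an AR(1) interannual anomaly; observation noise
  and Bernoulli cloud masking apply only to the emitted reflectances.
  The generator records the noise-free growing-season median per pixel
  and year as ground truth, so the compositing/extraction stages can be
  checked for exact inversion.

Within-plot and within-pixel noise magnitudes are free parameters (no
published within-plot variance to calibrate against); they were set once
to values that give chronology interannual SDs around 0.1 and NDVI
residual SDs below 0.01, i.e. the right order for temperate conifer
sites. The generator does not simulate spatial autocorrelation between
plots, sensor changes, or radiative transfer — so passing tests show the
*statistical machinery* is correct and the injected effects are
recoverable at realistic noise levels, not that any ecological
conclusion transfers to real imagery.

Because the event *magnitude* on growth is a fixed fraction rather than
proportional to the injected severity, full-pipeline model fits show SEV
(row-year severity) as the dominant predictor while SEV0 carries little
independent signal; SEV0-specific behaviour (coverage, sign recovery,
R² loss when omitted) is tested on data generated directly from the
linear model instead.

## Problem sizes used in tests

The acceptance-style checks run at desk scale: the spline response on a
330-year series; SPEI on the 33-year monthly record; SEA calibration
with 500 white-noise replicates × 1000 resamples; injection recovery on
the full 40-plot, 26-tree design; LMM recovery over 200 replicates of
400 rows; and the end-to-end determinism check as two complete default
pipeline runs (each well under a minute). These sizes keep the whole
suite fast while leaving every Monte-Carlo tolerance meaningful.
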