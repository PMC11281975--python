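"""Synthetic climate, ring-width, and reflectance-scene generators.

The generators emulate the statistical structure the downstream analysis
assumes: a temperate-conifer study design with two species (PCAB, PISY),
20 plots per species in four topographic categories, 33 years of climate
with injected high-SR / low-SM drought summers, age-trended ring widths
with climate coupling and multi-year drought legacies, and Landsat-like
red/NIR scenes whose NDVI carries a long-term trend, drought-year dips and
post-drought rebounds.

Injected drought years are made the most extreme JJA solar-radiation (and
lowest soil-moisture) summers of the record by construction — the study
design defines its events as the driest years, so the generator guarantees
the event-selection stage can identify them.

Everything is deterministic under a fixed seed; each generator derives an
independent child stream from it, so the three can be called in any order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig, SPECIES
from .greenness import growing_season_window
from .tree_ring import RingWidthSeries

_MONTH_EDGES = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DEFAULT_PIXEL_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_plot_metadata(config: SimulationConfig,
                       weights=DEFAULT_PIXEL_WEIGHTS) -> pd.DataFrame:
    """Plot table: one row per plot x pixel with overlap weights.

    Plots are spread evenly over the four categories (5 each at the default
    20 per species).
    """
    rows = []
    per_cat = config.n_plots_per_species // len(config.categories)
    for sp in SPECIES:
        k = 0
        for cat in config.categories:
            reps = per_cat + (1 if config.n_plots_per_species % len(config.categories)
                              > list(config.categories).index(cat) else 0)
            for r in range(reps):
                k += 1
                plot_id = f"{sp}_{cat}{r + 1}"
                for px, w in enumerate(weights):
                    rows.append(dict(plot_id=plot_id, species=sp, category=cat,
                                     pixel_id=f"{plot_id}_px{px}", weight=w))
        # trim/ignore overflow: plots beyond n_plots_per_species not produced
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def simulate_climate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily temperature plus monthly T/P/SR/SM tables.

    Daily T follows a sinusoidal annual cycle with AR(1) weather noise;
    monthly T is the exact mean of the daily values.  Monthly P, SR, SM get
    seasonal cycles with Gaussian noise.  Injected drought years have their
    JJA SR raised to at least ``sr_anomaly`` baseline SDs above the
    non-event mean (and above the highest background year), and JJA SM
    symmetrically depressed.
    """
    rng = _rng(config, 1)
    years = np.array(config.years)
    n_days = 365

    daily_rows = []
    monthly_T = {}
    eps = 0.0
    for y in years:
        doy = np.arange(1, n_days + 1)
        base = 8.0 - 10.0 * np.cos(2 * np.pi * (doy - 20) / 365.0)
        noise = np.empty(n_days)
        for d in range(n_days):
            eps = 0.7 * eps + rng.normal(0.0, 1.5 * np.sqrt(1 - 0.7 ** 2))
            noise[d] = eps
        t = base + noise
        daily_rows.append(pd.DataFrame({"year": y, "doy": doy, "T": t}))
        monthly_T[y] = [t[_MONTH_EDGES[m]:_MONTH_EDGES[m + 1]].mean()
                        for m in range(12)]
    daily = pd.concat(daily_rows, ignore_index=True)

    m = np.arange(1, 13)
    rows = []
    for y in years:
        p = np.maximum(0.0, 55.0 + 25.0 * np.sin(2 * np.pi * (m - 3.5) / 12.0)
                       + rng.normal(0.0, 15.0, 12))
        sr = np.maximum(0.0, 4.0e8 + 3.0e8 * np.sin(2 * np.pi * (m - 3.5) / 12.0)
                        + rng.normal(0.0, 3.0e7, 12))
        sm = np.maximum(1.0, 30.0 + 6.0 * np.cos(2 * np.pi * (m - 2.0) / 12.0)
                        + rng.normal(0.0, 2.0, 12))
        rows.append(pd.DataFrame({"year": y, "month": m, "T": monthly_T[y],
                                  "P": p, "SR": sr, "SM": sm}))
    monthly = pd.concat(rows, ignore_index=True)

    _inject_jja(monthly, "SR", config.drought_years, config.sr_anomaly, +1)
    _inject_jja(monthly, "SM", config.drought_years, config.sr_anomaly, -1)
    return daily, monthly


def _inject_jja(monthly: pd.DataFrame, var: str, event_years, n_sd: float,
                sign: int) -> None:
    """Shift JJA months of event years past mean + sign*n_sd*SD of the rest."""
    jja = monthly[monthly["month"].isin((6, 7, 8))]
    means = jja.groupby("year")[var].mean()
    bg = means.drop(index=list(event_years))
    mu, sd = bg.mean(), bg.std(ddof=1)
    # events differ in severity (real dry spells do); spacing 0.35 SD keeps
    # SEV0 a non-degenerate regressor while every event clears the floor
    for i, y in enumerate(sorted(event_years)):
        extra = (0.35 * i + 1e-3) * sd
        if sign > 0:
            target = max(mu + n_sd * sd, bg.max() + 0.1 * sd) + extra
        else:
            target = min(mu - n_sd * sd, bg.min() - 0.1 * sd) - extra
        cur = means.loc[y]
        delta = target - cur
        if sign * delta > 0:
            sel = (monthly["year"] == y) & monthly["month"].isin((6, 7, 8))
            monthly.loc[sel, var] += delta


def event_multipliers(config: SimulationConfig) -> pd.Series:
    """True multiplicative event profile on growth: drop at lag 0, legacy
    fractions at lags 1..4, compounding across overlapping events."""
    years = np.array(config.years)
    mult = np.ones(len(years), dtype=float)
    for e in config.drought_years:
        for lag, frac in [(0, config.growth_drop)] + [
                (k + 1, f) for k, f in enumerate(config.legacy)]:
            y = e + lag
            if config.year_start <= y <= config.year_end:
                mult[y - config.year_start] *= (1.0 - frac)
    return pd.Series(mult, index=years, name="growth_multiplier")


def simulate_ring_widths(monthly: pd.DataFrame, metadata: pd.DataFrame,
                         config: SimulationConfig) -> list[RingWidthSeries]:
    """Ring widths: age curve x climate coupling x event profile x noise.

    width(t) = (A exp(-age/tau) + c) * (1 + b_sr z_SR + b_sm z_SM)
               * event multiplier * lognormal AR(1) noise,
    with z_* the standardized JJA SR/SM anomalies of year t.
    """
    if config.age_amp <= 0 or config.age_tau <= 0 or config.age_base <= 0:
        raise ValueError("age-curve parameters must be positive")
    rng = _rng(config, 2)
    years = np.array(config.years)
    jja = monthly[monthly["month"].isin((6, 7, 8))]
    z = {}
    for var in ("SR", "SM"):
        s = jja.groupby("year")[var].mean().reindex(years)
        z[var] = ((s - s.mean()) / s.std(ddof=1)).to_numpy()
    climate_factor = np.maximum(
        0.05, 1.0 + config.coupling_sr * z["SR"] + config.coupling_sm * z["SM"])
    mult = event_multipliers(config).to_numpy()

    plots = metadata.drop_duplicates("plot_id")
    out = []
    n_y = len(years)
    sd, phi = config.noise.ring_sd, config.noise.ring_ar
    for plot_id in plots["plot_id"]:
        for k in range(config.n_trees_per_plot):
            age0 = int(rng.integers(60, 121))
            ages = age0 + np.arange(n_y)
            trend = config.age_amp * np.exp(-ages / config.age_tau) + config.age_base
            if sd > 0:
                eps = np.empty(n_y)
                e = rng.normal(0.0, sd)
                for t in range(n_y):
                    e = phi * e + rng.normal(0.0, sd * np.sqrt(1 - phi ** 2))
                    eps[t] = e
                noise = np.exp(eps - 0.5 * sd ** 2)
            else:
                rng.normal(size=n_y + 1)   # keep the stream aligned
                noise = np.ones(n_y)
            w = trend * climate_factor * mult * noise
            # Tucson series ids are limited to 8 characters
            sp, cat = plot_id.split("_")
            tid = f"{sp[:2]}{cat}{k + 1:03d}"
            out.append(RingWidthSeries(tid, plot_id, int(years[0]), w))
    return out


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def _ndvi_event_profile(config: SimulationConfig) -> pd.Series:
    years = np.array(config.years)
    eff = np.zeros(len(years))
    for e in config.drought_years:
        for lag, d in [(0, -config.ndvi_drop), (1, config.ndvi_rebound),
                       (2, config.ndvi_rebound)]:
            y = e + lag
            if config.year_start <= y <= config.year_end:
                eff[y - config.year_start] += d
    return pd.Series(eff, index=years, name="ndvi_effect")


def simulate_scenes(daily: pd.DataFrame, metadata: pd.DataFrame,
                    config: SimulationConfig,
                    scene_doys=tuple(range(100, 271, 10)),
                    thresholds: dict | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-scene red/NIR reflectance with clouds, plus ground truth.

    The per-pixel NDVI signal is base level + linear trend + seasonal shape
    + event profile + an AR(1) interannual plot anomaly; observation noise
    and cloud masking apply only to the emitted reflectances.  Ground truth
    records the per-year, per-pixel growing-season median of the noise-free
    signal and its overlap-weighted plot mean.

    Returns (scenes, truth, n_clipped): scenes has one row per
    scene x pixel, truth one row per plot x pixel x year (pixel_id == ''
    marks the plot-level weighted value).
    """
    from .config import SPECIES_THRESHOLDS
    thresholds = thresholds or SPECIES_THRESHOLDS
    rng = _rng(config, 3)
    years = np.array(config.years)
    event = _ndvi_event_profile(config)
    base_by_species = {"PCAB": 0.70, "PISY": 0.62}

    windows = {}
    for sp in SPECIES:
        for y in years:
            windows[(sp, y)] = growing_season_window(daily, int(y), thresholds[sp])

    scene_rows = []
    truth_rows = []
    n_clipped = 0
    sd, phi = config.noise.ndvi_sd, config.noise.ndvi_ar
    for plot_id, grp in metadata.groupby("plot_id", sort=True):
        sp = grp["species"].iloc[0]
        pixels = grp["pixel_id"].tolist()
        weights = grp["weight"].to_numpy(dtype=float)
        plot_base = base_by_species[sp] + rng.normal(0.0, 0.01)
        px_offset = rng.normal(0.0, 0.005, len(pixels))
        # interannual AR(1) anomaly, part of the signal
        anom = np.empty(len(years))
        a = rng.normal(0.0, 0.01)
        for t in range(len(years)):
            a = phi * a + rng.normal(0.0, 0.01 * np.sqrt(1 - phi ** 2))
            anom[t] = a

        plot_truth = {}
        for yi, y in enumerate(years):
            win = windows[(sp, int(y))]
            sig_year = (plot_base + config.ndvi_trend * (y - years[0])
                        + event.loc[y] + anom[yi])
            per_pixel_medians = []
            for pi, px in enumerate(pixels):
                doys = np.array(scene_doys)
                seasonal = 0.04 * np.sin(np.pi * (doys - 90) / 200.0)
                signal = sig_year + px_offset[pi] + seasonal
                if sd > 0:
                    noise = np.empty(len(doys))
                    e = rng.normal(0.0, sd)
                    for t in range(len(doys)):
                        e = phi * e + rng.normal(0.0, sd * np.sqrt(1 - phi ** 2))
                        noise[t] = e
                else:
                    rng.normal(size=len(doys) + 1)
                    noise = np.zeros(len(doys))
                obs = np.clip(signal + noise, -1.0, 1.0)
                clouds = rng.random(len(doys)) < config.cloud_fraction
                total = 0.5
                nir = total * (1.0 + obs) / 2.0
                red = total * (1.0 - obs) / 2.0
                n_clipped += int(np.sum((nir < 0) | (nir > 1)
                                        | (red < 0) | (red > 1)))
                nir, red = np.clip(nir, 0, 1), np.clip(red, 0, 1)
                for di, doy in enumerate(doys):
                    scene_rows.append((
                        f"S{y}D{doy:03d}", int(y), int(doy), px,
                        np.nan if clouds[di] else red[di],
                        np.nan if clouds[di] else nir[di],
                        int(clouds[di])))
                if win is None:
                    med = np.nan
                else:
                    inwin = (doys >= win[0]) & (doys <= win[1])
                    med = float(np.median(signal[inwin])) if inwin.any() else np.nan
                per_pixel_medians.append(med)
                truth_rows.append(dict(plot_id=plot_id, pixel_id=px,
                                       year=int(y), ndvi=med))
            pm = np.array(per_pixel_medians)
            ok = ~np.isnan(pm)
            plot_truth[int(y)] = (float(np.sum(pm[ok] * weights[ok])
                                        / weights[ok].sum()) if ok.any()
                                  else np.nan)
        for y, v in plot_truth.items():
            truth_rows.append(dict(plot_id=plot_id, pixel_id="", year=y, ndvi=v))

    scenes = pd.DataFrame(scene_rows, columns=[
        "scene_id", "year", "doy", "pixel_id", "red", "nir", "cloud_flag"])
    truth = pd.DataFrame(truth_rows)
    return scenes, truth, n_clipped
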