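"""Annual growing-season NDVI series per plot from scene stacks.

The chain is: per-scene NDVI -> growing-season subset (thermal start,
fixed 30 September end) -> per-pixel annual median composite ->
overlap-weighted plot mean -> linear detrending to residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AnnualGreenness:
    plot_id: str
    years: np.ndarray
    ndvi: np.ndarray       # annual growing-season composite, [-1, 1]
    residual: np.ndarray   # residual from the per-plot linear trend
    trend: tuple[float, float] = (np.nan, np.nan)  # (intercept, slope/yr)


def compute_ndvi(nir, red):
    """(NIR - Red) / (NIR + Red); NaN where the denominator is zero."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def season_end_doy(year: int) -> int:
    """DOY of 30 September (273 in common years, 274 in leap years)."""
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return 274 if leap else 273


def growing_season_window(daily_t: pd.DataFrame, year: int,
                          threshold_c: float) -> tuple[int, int] | None:
    """Thermal growing-season window for one year.

    Start: first DOY d >= 6 whose five *preceding* days (d-5..d-1) have mean
    temperature strictly above the threshold.  End: 30 September.  Returns
    None when no day qualifies before the end date (empty season).

    ``daily_t`` needs columns year, doy, T.
    """
    sub = daily_t[daily_t["year"] == year].sort_values("doy")
    t = sub["T"].to_numpy()
    doy = sub["doy"].to_numpy()
    if len(t) == 0 or doy[0] != 1:
        raise ValueError(f"daily temperature must start at DOY 1 of {year}")
    end = season_end_doy(year)
    # rolling mean of the 5 preceding days, aligned to day d (index d-1)
    c = np.concatenate([[0.0], np.cumsum(t)])
    for d in range(6, min(int(doy[-1]), end) + 1):
        if (c[d - 1] - c[d - 6]) / 5.0 > threshold_c:
            return d, end
    return None


def annual_median_composite(scenes: pd.DataFrame, window: tuple[int, int],
                            year: int) -> pd.Series:
    """Per-pixel median NDVI over unmasked scene dates inside the window.

    ``scenes`` needs columns year, doy, pixel_id, red, nir, cloud_flag.
    Pixels with no usable observation come back NaN.
    """
    start, end = window
    sub = scenes[(scenes["year"] == year) & (scenes["doy"] >= start)
                 & (scenes["doy"] <= end) & (scenes["cloud_flag"] == 0)]
    if sub.empty:
        return pd.Series(dtype=float, name=year)
    ndvi = compute_ndvi(sub["nir"].to_numpy(), sub["red"].to_numpy())
    return (pd.Series(ndvi, index=sub["pixel_id"].to_numpy())
            .groupby(level=0).median().rename(year))


def extract_plot_series(composites: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Overlap-weighted plot mean per year.

    ``composites``: rows = pixel_id, columns = years.  Weights are
    renormalized over non-missing pixels each year; a year with no usable
    pixel is NaN.
    """
    weights = weights.reindex(composites.index)
    if not (weights.fillna(0) >= 0).all() or not (weights.fillna(0) > 0).any():
        raise ValueError("weights must be non-negative with at least one positive")
    out = {}
    for year in composites.columns:
        col = composites[year]
        ok = col.notna() & weights.notna() & (weights > 0)
        if not ok.any():
            out[year] = np.nan
            continue
        w = weights[ok] / weights[ok].sum()
        out[year] = float((col[ok] * w).sum())
    return pd.Series(out, name="ndvi")


def detrend_linear_residuals(plot_id: str, annual: pd.Series) -> AnnualGreenness:
    """OLS of NDVI on calendar year; keep the residuals.

    Requires at least 3 non-missing years.  The trend removes slow drivers
    of greenness (canopy densification, CO2 fertilization) so that the
    residuals carry the interannual climate signal.
    """
    years = np.asarray(annual.index, dtype=float)
    vals = annual.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 3:
        raise ValueError(f"{plot_id}: need >=3 years to fit a trend, "
                         f"got {int(ok.sum())}")
    slope, intercept = np.polyfit(years[ok], vals[ok], 1)
    resid = np.where(ok, vals - (intercept + slope * years), np.nan)
    return AnnualGreenness(plot_id, years.astype(int), vals, resid,
                           trend=(float(intercept), float(slope)))
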