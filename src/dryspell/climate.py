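"""Drought indexing: Thornthwaite PET, SPEI, seasonal means, severities,
and selection of non-consecutive drought years.

Monthly climate tables carry T (°C), P (mm), SR (J/m²), SM (kg/m²).
Seasons: JJA = June-August, GS = May-September.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

SEASONS = {"JJA": (6, 7, 8), "GS": (5, 6, 7, 8, 9)}

_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


@dataclass
class EventSet:
    """Selected drought years for one site, ordered by calendar year."""

    site_id: str
    variable: str                 # SR or SM
    years: list[int]
    severities: list[float]

    def __post_init__(self) -> None:
        order = np.argsort(self.years)
        self.years = [int(self.years[i]) for i in order]
        self.severities = [float(self.severities[i]) for i in order]
        for a, b in zip(self.years, self.years[1:]):
            if b - a < 2:
                raise ValueError(f"event years {a}, {b} are consecutive")


def day_length_hours(latitude: float, doy) -> np.ndarray:
    """Astronomical day length (h) from latitude and day of year."""
    doy = np.asarray(doy, dtype=float)
    decl = 0.409 * np.sin(2 * np.pi * doy / 365.25 - 1.39)
    lat = math.radians(latitude)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h)


def thornthwaite_pet(monthly: pd.DataFrame, latitude: float) -> pd.Series:
    """Classical Thornthwaite monthly PET (mm).

    Heat index I is computed per year from that year's 12 monthly T values;
    PET is zero for freezing months, follows 16*(10T/I)**a below 26.5 °C,
    and the Willmott hot-month polynomial above.  Each month is scaled by
    day length / 12 and month length / 30.
    """
    if not -90 <= latitude <= 90:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    out = pd.Series(np.nan, index=monthly.index, name="PET")
    for year, grp in monthly.groupby("year"):
        if sorted(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"year {year}: all 12 months required for the heat index")
        t = grp.sort_values("month")["T"].to_numpy(dtype=float)
        i_year = np.sum(np.where(t > 0, (np.maximum(t, 0) / 5.0) ** 1.514, 0.0))
        if i_year <= 0:
            out.loc[grp.index] = 0.0
            continue
        a = (6.75e-7 * i_year**3 - 7.71e-5 * i_year**2
             + 1.792e-2 * i_year + 0.49239)
        pet = np.zeros(12)
        warm = (t > 0) & (t < 26.5)
        pet[warm] = 16.0 * (10.0 * t[warm] / i_year) ** a
        hot = t >= 26.5
        pet[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2
        dl = day_length_hours(latitude, _MID_MONTH_DOY)
        pet *= (dl / 12.0) * (_DAYS_IN_MONTH / 30.0)
        out.loc[grp.sort_values("month").index] = pet
    return out


def _pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments w_s = E[X (1-F)^s], s = 0..2."""
    x = np.sort(x)
    n = len(x)
    i = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum(x * (n - i)) / (n * (n - 1))
    w2 = np.sum(x * (n - i) * (n - i - 1)) / (n * (n - 1) * (n - 2))
    return w0, w1, w2


def _loglogistic_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Three-parameter log-logistic / generalized-logistic fit by unbiased
    probability-weighted moments.

    Uses the Hosking generalized-logistic parametrization (location xi,
    scale alpha, shape kappa = -tau3), which is the log-logistic for
    kappa < 0 and remains well defined for either skew sign.
    """
    w0, w1, w2 = _pwm(x)
    l1 = w0
    l2 = w0 - 2 * w1
    l3 = w0 - 6 * w1 + 6 * w2
    kappa = -l3 / l2
    if abs(kappa) < 1e-8:
        alpha = l2
        xi = l1
        return xi, alpha, 0.0
    gk = kappa * math.pi / math.sin(kappa * math.pi)
    alpha = l2 / gk
    xi = l1 - (alpha / kappa) * (1.0 - gk)
    return xi, alpha, kappa


def _glo_cdf(x: np.ndarray, xi: float, alpha: float, kappa: float) -> np.ndarray:
    """Generalized-logistic CDF; values outside the support clamp to 0/1."""
    x = np.asarray(x, dtype=float)
    if kappa == 0.0:
        y = (x - xi) / alpha
    else:
        arg = 1.0 - kappa * (x - xi) / alpha
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)) / kappa,
                         np.where(kappa > 0, np.inf, -np.inf))
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


def accumulate(series: pd.Series, scale: int) -> pd.Series:
    """Rolling sum over ``scale`` months ending in (and including) each month."""
    return series.rolling(scale).sum()


def spei(monthly: pd.DataFrame, pet: pd.Series, scale: int = 4,
         calibration: tuple[int, int] | None = None) -> pd.Series:
    """Standardised Precipitation-Evapotranspiration Index.

    The climatic water balance D = P - PET is accumulated over ``scale``
    months; for each calendar month a three-parameter log-logistic is fitted
    over the calibration years by unbiased probability-weighted moments, and
    SPEI is the standard-normal quantile of the fitted CDF.
    """
    df = monthly.sort_values(["year", "month"]).copy()
    df["D"] = df["P"].to_numpy() - pet.loc[df.index].to_numpy()
    df["Dk"] = accumulate(df["D"], scale)
    if calibration is None:
        calibration = (int(df["year"].min()), int(df["year"].max()))
    out = pd.Series(np.nan, index=df.index, name="SPEI")
    for m in range(1, 13):
        sel = df["month"] == m
        cal = sel & df["year"].between(*calibration) & df["Dk"].notna()
        x = df.loc[cal, "Dk"].to_numpy()
        if len(x) < 20:
            raise ValueError(f"month {m}: {len(x)} calibration values < 20")
        if np.ptp(x) == 0:
            raise ValueError(f"month {m}: degenerate accumulated series")
        xi, alpha, kappa = _loglogistic_fit(x)
        z = df.loc[sel, "Dk"].to_numpy()
        cdf = np.clip(_glo_cdf(z, xi, alpha, kappa), 1e-6, 1 - 1e-6)
        vals = norm.ppf(cdf)
        vals[np.isnan(z)] = np.nan
        out.loc[df.index[sel]] = vals
    return out.loc[monthly.index]


def seasonal_means(monthly: pd.DataFrame, variable: str,
                   season: str = "JJA") -> pd.Series:
    """Arithmetic mean of the season's monthly values, one value per year.

    Years with any season month missing come back NaN.
    """
    months = SEASONS[season] if isinstance(season, str) else tuple(season)
    sub = monthly[monthly["month"].isin(months)]
    def agg(g):
        if len(g) < len(months) or g[variable].isna().any():
            return np.nan
        return g[variable].mean()
    return sub.groupby("year").apply(agg, include_groups=False).rename(variable)


def severity_anomalies(seasonal: pd.Series, baseline: tuple[int, int] | None = None,
                       standardize: bool = True) -> pd.Series:
    """Anomaly of a seasonal series from its baseline mean.

    Standardized (divided by the baseline SD) by default so that severities
    from different variables and units are comparable regressors.
    """
    years = np.asarray(seasonal.index, dtype=int)
    if baseline is None:
        baseline = (int(years.min()), int(years.max()))
    base = seasonal[(years >= baseline[0]) & (years <= baseline[1])].dropna()
    if len(base) < 5:
        raise ValueError(f"baseline {baseline} has {len(base)} years < 5")
    anom = seasonal - base.mean()
    if standardize:
        anom = anom / base.std(ddof=1)
    return anom.rename("severity")


def select_drought_years(severity: pd.Series, n: int = 4,
                         direction: str = "max", site_id: str = "site",
                         variable: str = "SR") -> EventSet:
    """Greedy extreme-first selection of non-consecutive drought years.

    Repeatedly takes the most extreme remaining year whose neighbours
    (±1 year) are not already selected; ties break toward the earlier year.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    s = severity.dropna()
    years = np.asarray(s.index, dtype=int)
    vals = s.to_numpy(dtype=float)
    order = np.lexsort((years, -vals if direction == "max" else vals))
    chosen: list[int] = []
    for i in order:
        y = int(years[i])
        if any(abs(y - c) <= 1 for c in chosen):
            continue
        chosen.append(y)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(f"cannot select {n} non-consecutive years "
                         f"from {len(s)} candidates")
    sev = [float(s.loc[y]) for y in chosen]
    return EventSet(site_id, variable, chosen, sev)
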