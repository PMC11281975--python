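"""Superposed epoch analysis and climate-growth correlations.

SEA stacks a response series around event years and reports, for each lag
in -L..+L, the mean departure from the overall series mean.  Significance
comes from a resampling null: random event sets of the same size (by
default also non-consecutive, matching the sampling frame of the real
events) drawn from all years whose full lag window fits the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate import EventSet


@dataclass
class SEAResult:
    series_id: str
    lags: np.ndarray
    departure: np.ndarray
    p: np.ndarray
    n_events: int
    resamples: int
    seed: int
    dropped_events: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"series_id": self.series_id, "lag": self.lags,
                             "departure": self.departure, "p": self.p})


def _draw_event_sets(rng: np.random.Generator, eligible: np.ndarray, k: int,
                     n_sets: int, non_consecutive: bool) -> np.ndarray:
    """(n_sets, k) array of random event years, without replacement."""
    m = len(eligible)
    # rank-order trick: argsort of uniforms = random k-subset per row
    u = rng.random((n_sets, m))
    picks = np.sort(eligible[np.argsort(u, axis=1)[:, :k]], axis=1)
    if non_consecutive:
        bad = (np.diff(picks, axis=1) <= 1).any(axis=1)
        while bad.any():
            u = rng.random((int(bad.sum()), m))
            picks[bad] = np.sort(eligible[np.argsort(u, axis=1)[:, :k]], axis=1)
            bad = (np.diff(picks, axis=1) <= 1).any(axis=1)
    return picks


def superposed_epoch(years: np.ndarray, values: np.ndarray, events: EventSet,
                     lag: int = 4, resamples: int = 1000, seed: int = 0,
                     non_consecutive_null: bool = True,
                     series_id: str = "series") -> SEAResult:
    """SEA departures for lags -lag..+lag with an empirical two-sided p.

    Events whose window sticks out of the series are dropped (warning kept
    in the result); p-values use the add-one permutation form
    (1 + #{|null| >= |obs|}) / (1 + resamples), which floors p at
    1/(resamples+1).
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    lags = np.arange(-lag, lag + 1)
    y0 = int(years[0])
    kept, dropped = [], []
    for e in events.years:
        if e - lag >= years[0] and e + lag <= years[-1]:
            kept.append(e)
        else:
            dropped.append(e)
    if not kept:
        raise ValueError("all events fall outside the usable series support")
    mean = float(np.nanmean(values))
    ev_idx = np.array([e - y0 for e in kept])
    departure = values[ev_idx[:, None] + lags[None, :]].mean(axis=0) - mean

    eligible = years[(years - lag >= years[0]) & (years + lag <= years[-1])]
    rng = np.random.default_rng(seed)
    picks = _draw_event_sets(rng, eligible, len(kept), resamples,
                             non_consecutive_null)
    null = values[(picks - y0)[:, :, None] + lags[None, None, :]].mean(axis=1) - mean
    count = (np.abs(null) >= np.abs(departure)[None, :]).sum(axis=0)
    p = (1.0 + count) / (1.0 + resamples)
    return SEAResult(series_id, lags, departure, p, len(kept), resamples,
                     seed, dropped)


def climate_growth_correlations(response: pd.Series, climate: pd.DataFrame,
                                offsets=(0, -1)) -> pd.DataFrame:
    """Pearson correlations of a response with seasonal climate series.

    ``climate`` is a tidy frame with columns year, variable, season, value.
    Offset -1 correlates the response with the previous year's climate.
    Zero-variance pairings return NaN r with a flag.
    """
    rows = []
    r_years = np.asarray(response.index, dtype=int)
    for (var, season), grp in climate.groupby(["variable", "season"]):
        cs = pd.Series(grp["value"].to_numpy(), index=grp["year"].to_numpy())
        for off in offsets:
            # climate year = response year + offset
            aligned = cs.reindex(r_years + off).to_numpy()
            resp = response.to_numpy(dtype=float)
            ok = ~np.isnan(aligned) & ~np.isnan(resp)
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"{var}/{season} offset {off}: n={n} < 3")
            x, y = aligned[ok], resp[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(dict(variable=var, season=season, offset=off,
                                 r=np.nan, p=np.nan, n=n, degenerate=True))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(variable=var, season=season, offset=off,
                             r=float(r), p=float(p), n=n, degenerate=False))
    return pd.DataFrame(rows)
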