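#!/usr/bin/env python
"""Superposed epoch analysis around the drought years.

Stacks each plot's tree-ring index and NDVI residual series on the
selected events (lags -4..+4, departures from the series mean) and tests
each lag against 1000 random non-consecutive event sets.  Also computes
Pearson correlations of every series with the seasonal climate variables
in the current and previous year.  Writes sea.csv and correlations.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dryspell.climate import EventSet
from dryspell.epoch import climate_growth_correlations, superposed_epoch

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results" / "analysis"
SEED = 1


def main() -> None:
    ev_raw = json.loads((RES / "events.json").read_text())
    events = EventSet("site", ev_raw["variable"], ev_raw["years"],
                      ev_raw["severities"])
    chron = pd.read_csv(RES / "chronologies.csv")
    green = pd.read_csv(RES / "greenness.csv")
    seasonal = pd.read_csv(RES / "seasonal_climate.csv")

    ss = np.random.SeedSequence([SEED, 99])
    series = [("TRI", pid, g.set_index("year")["index"])
              for pid, g in chron.groupby("plot_id")]
    series += [("NDVI", pid, g.set_index("year")["residual"])
               for pid, g in green.groupby("plot_id")]
    child = iter(ss.generate_state(len(series)))

    sea_frames, corr_frames = [], []
    for label, pid, s in series:
        r = superposed_epoch(s.index.to_numpy(), s.to_numpy(), events,
                             lag=4, resamples=1000,
                             seed=int(next(child)) % (2**31),
                             series_id=f"{label}:{pid}")
        sea_frames.append(r.to_frame())
        c = climate_growth_correlations(s, seasonal)
        c.insert(0, "series_id", f"{label}:{pid}")
        corr_frames.append(c)
    sea = pd.concat(sea_frames, ignore_index=True)
    sea.to_csv(RES / "sea.csv", index=False)
    pd.concat(corr_frames, ignore_index=True).to_csv(
        RES / "correlations.csv", index=False)

    sea["compartment"] = sea["series_id"].str.split(":").str[0]
    for comp, g in sea.groupby("compartment"):
        lag0 = g[g["lag"] == 0]
        n_sig = int((lag0["p"] < 0.05).sum())
        print(f"{comp}: lag-0 departure {lag0['departure'].mean():+.3f} "
              f"(significant at p<0.05 in {n_sig}/{len(lag0)} plots)")
        lag1 = g[g["lag"] == 1]
        print(f"      lag-1 departure {lag1['departure'].mean():+.3f} "
              f"({int((lag1['p'] < 0.05).sum())}/{len(lag1)} significant)")
    print(f"-> {RES / 'sea.csv'}")


if __name__ == "__main__":
    main()
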