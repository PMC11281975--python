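#!/usr/bin/env python
"""Derive drought indices and select the drought years.

Thornthwaite PET from monthly temperature, SPEI at the 4-month scale,
JJA / growing-season (May-September) means of all variables, standardized
JJA solar-radiation severities, and the greedy non-consecutive selection
of the four most severe drought years.  Writes seasonal_climate.csv,
severity.csv and events.json.
"""

import json
from pathlib import Path

import pandas as pd

from dryspell.climate import (seasonal_means, select_drought_years,
                              severity_anomalies, spei, thornthwaite_pet)

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results" / "analysis"
LATITUDE = 49.5


def main() -> None:
    monthly = pd.read_csv(RES / "inputs" / "monthly_climate.csv")
    pet = thornthwaite_pet(monthly, LATITUDE)
    monthly["PET"] = pet
    monthly["SPEI"] = spei(monthly, pet, scale=4)

    frames = []
    for var in ("T", "P", "SR", "SM", "SPEI"):
        for season in ("JJA", "GS"):
            s = seasonal_means(monthly, var, season)
            frames.append(pd.DataFrame({"year": s.index, "variable": var,
                                        "season": season,
                                        "value": s.to_numpy()}))
    seasonal = pd.concat(frames, ignore_index=True)
    seasonal.to_csv(RES / "seasonal_climate.csv", index=False)

    jja_sr = seasonal.query("variable == 'SR' and season == 'JJA'")
    sev = severity_anomalies(pd.Series(jja_sr["value"].to_numpy(),
                                       index=jja_sr["year"].to_numpy()))
    sev.rename_axis("year").to_csv(RES / "severity.csv")
    events = select_drought_years(sev, n=4, direction="max", variable="SR")
    (RES / "events.json").write_text(json.dumps(
        {"variable": events.variable, "years": events.years,
         "severities": events.severities}, indent=2))

    print(f"summer PET range "
          f"{monthly[monthly['month'].isin((6, 7, 8))]['PET'].min():.0f}-"
          f"{monthly[monthly['month'].isin((6, 7, 8))]['PET'].max():.0f} mm")
    print("selected drought years (highest JJA SR, non-consecutive): "
          + ", ".join(f"{y} (z={s:.2f})"
                      for y, s in zip(events.years, events.severities)))
    print(f"-> {RES / 'events.json'}")


if __name__ == "__main__":
    main()
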