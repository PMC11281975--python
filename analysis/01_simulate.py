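#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the study design: 33 years (1985-2017) of daily/monthly climate
with four injected non-consecutive drought summers (1994, 2003, 2006,
2015), 20 plots for each of two conifer species (PCAB, PISY) spread over
four topographic categories, >=26 trees per plot with age-trended,
climate-coupled ring widths, and Landsat-like red/NIR scene stacks with
clouds.  Writes everything under results/analysis/inputs/.
"""

import argparse
from pathlib import Path

from dryspell.config import SimulationConfig
from dryspell.synthetic import (make_plot_metadata, simulate_climate,
                                simulate_ring_widths, simulate_scenes)
from dryspell.tree_ring import write_rwl

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis" / "inputs"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    meta = make_plot_metadata(cfg)
    daily, monthly = simulate_climate(cfg)
    rws = simulate_ring_widths(monthly, meta, cfg)
    scenes, truth, n_clip = simulate_scenes(daily, meta, cfg)

    meta.to_csv(OUT / "metadata.csv", index=False)
    daily.to_csv(OUT / "daily_climate.csv", index=False)
    monthly.to_csv(OUT / "monthly_climate.csv", index=False)
    scenes.to_csv(OUT / "scenes.csv", index=False)
    truth.to_csv(OUT / "ndvi_truth.csv", index=False)
    (OUT / "rwl").mkdir(exist_ok=True)
    for plot_id in meta["plot_id"].unique():
        write_rwl([s for s in rws if s.plot_id == plot_id],
                  OUT / "rwl" / f"{plot_id}.rwl")

    n_plots = meta["plot_id"].nunique()
    print(f"seed {seed}: {n_plots} plots, {len(rws)} trees, "
          f"{len(scenes)} scene-pixel records "
          f"({scenes['cloud_flag'].mean():.0%} cloud-masked, "
          f"{n_clip} reflectances clipped)")
    print(f"inputs -> {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
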