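"""End-to-end orchestration: simulate (or load) inputs, build chronologies
and greenness series, derive drought indices, select events, run SEA,
fit the response models, and write a reproducible output bundle.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import (EventSet, seasonal_means, select_drought_years,
                      severity_anomalies, spei, thornthwaite_pet)
from .config import PipelineConfig, SPECIES
from .epoch import climate_growth_correlations, superposed_epoch
from .greenness import (annual_median_composite, detrend_linear_residuals,
                        extract_plot_series, growing_season_window)
from .models import (VARIANTS, build_response_table, fit_random_intercept_lmm,
                     model_metrics, resilience_metrics)
from .synthetic import (make_plot_metadata, simulate_climate,
                        simulate_ring_widths, simulate_scenes)
from .tree_ring import build_chronology, read_rwl, spline_detrend, write_rwl

log = logging.getLogger("dryspell")

_FLOAT_FMT = "%.8g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of the main result tables.

    All outputs land under ``config.out_dir``; a manifest records the
    configuration, seed, package version and per-stage status so a run can
    be reproduced byte for byte.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "stages": {}, "warnings": []}
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                              default=str))
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.time() - t0, 3)}
            log.info("stage %s done in %.2fs", name, time.time() - t0)
        return deco

    # ------------------------------------------------------------------ inputs
    inputs = out / "inputs"

    @stage("inputs")
    def _inputs():
        nonlocal inputs
        if config.synthetic:
            sim = config.simulation
            inputs.mkdir(exist_ok=True)
            meta = make_plot_metadata(sim)
            daily, monthly = simulate_climate(sim)
            rws = simulate_ring_widths(monthly, meta, sim)
            scenes, truth, n_clip = simulate_scenes(daily, meta, sim)
            _write(meta, inputs / "metadata.csv")
            _write(daily, inputs / "daily_climate.csv")
            _write(monthly, inputs / "monthly_climate.csv")
            _write(scenes, inputs / "scenes.csv")
            _write(truth, inputs / "ndvi_truth.csv")
            rwl_dir = inputs / "rwl"
            rwl_dir.mkdir(exist_ok=True)
            for plot_id in meta["plot_id"].unique():
                write_rwl([s for s in rws if s.plot_id == plot_id],
                          rwl_dir / f"{plot_id}.rwl")
            manifest["stages"].setdefault("inputs", {})
            manifest["warnings"].append(f"{n_clip} reflectances clipped to [0,1]")
            results["metadata"] = meta
            results["daily"] = daily
            results["monthly"] = monthly
            results["scenes"] = scenes
            results["ring_series"] = rws
        else:
            results["metadata"] = pd.read_csv(config.metadata_path)
            results["daily"] = pd.read_csv(config.daily_climate_path)
            results["monthly"] = pd.read_csv(config.monthly_climate_path)
            results["scenes"] = pd.read_csv(config.scenes_path)
            rws = []
            for f in sorted(Path(config.rwl_dir).glob("*.rwl")):
                rws.extend(read_rwl(f))
            results["ring_series"] = rws

    # ------------------------------------------------------------- chronologies
    @stage("chronologies")
    def _chron():
        by_plot: dict[str, list] = {}
        for s in results["ring_series"]:
            try:
                by_plot.setdefault(s.plot_id, []).append(
                    spline_detrend(s, config.spline_wavelength))
            except ValueError as e:
                manifest["warnings"].append(str(e))
        chron = {p: build_chronology(d, p, config.min_sample_depth)
                 for p, d in sorted(by_plot.items())}
        results["chronologies"] = chron
        _write(pd.concat([pd.DataFrame({"plot_id": c.plot_id, "year": c.years,
                                        "index": c.index,
                                        "sample_depth": c.sample_depth})
                          for c in chron.values()], ignore_index=True),
               out / "chronologies.csv")

    # ---------------------------------------------------------------- greenness
    @stage("greenness")
    def _green():
        meta = results["metadata"]
        scenes = results["scenes"]
        daily = results["daily"]
        greenness = {}
        window_rows = []
        for plot_id, grp in meta.groupby("plot_id", sort=True):
            sp = grp["species"].iloc[0]
            thr = config.species_thresholds[sp]
            weights = grp.set_index("pixel_id")["weight"]
            sub = scenes[scenes["pixel_id"].isin(weights.index)]
            cols = {}
            for year in sorted(sub["year"].unique()):
                win = growing_season_window(daily, int(year), thr)
                if win is None:
                    manifest["warnings"].append(
                        f"{plot_id} {year}: empty growing season")
                    window_rows.append((plot_id, int(year), np.nan, np.nan))
                    continue
                window_rows.append((plot_id, int(year), *win))
                cols[int(year)] = annual_median_composite(sub, win, int(year))
            comp = pd.DataFrame(cols).reindex(weights.index)
            annual = extract_plot_series(comp, weights)
            greenness[plot_id] = detrend_linear_residuals(plot_id, annual)
        results["greenness"] = greenness
        _write(pd.concat([pd.DataFrame({"plot_id": g.plot_id, "year": g.years,
                                        "ndvi": g.ndvi, "residual": g.residual})
                          for g in greenness.values()], ignore_index=True),
               out / "greenness.csv")
        _write(pd.DataFrame(window_rows, columns=["plot_id", "year",
                                                  "start_doy", "end_doy"]),
               out / "season_windows.csv")

    # ------------------------------------------------------------------ climate
    @stage("climate_indices")
    def _climate():
        monthly = results["monthly"].copy()
        pet = thornthwaite_pet(monthly, config.latitude)
        monthly["PET"] = pet
        monthly["SPEI"] = spei(monthly, pet, scale=config.spei_scale)
        seasonal = []
        for var in ("T", "P", "SR", "SM", "SPEI"):
            for season in ("JJA", "GS"):
                s = seasonal_means(monthly, var, season)
                seasonal.append(pd.DataFrame({"year": s.index, "variable": var,
                                              "season": season,
                                              "value": s.to_numpy()}))
        seasonal = pd.concat(seasonal, ignore_index=True)
        results["seasonal"] = seasonal
        _write(seasonal, out / "seasonal_climate.csv")

        jja = seasonal[(seasonal["variable"] == config.event_variable)
                       & (seasonal["season"] == "JJA")]
        sev = severity_anomalies(pd.Series(jja["value"].to_numpy(),
                                           index=jja["year"].to_numpy()))
        results["severity"] = sev
        direction = "max" if config.event_variable == "SR" else "min"
        events = select_drought_years(sev, n=config.n_events,
                                      direction=direction,
                                      variable=config.event_variable)
        results["events"] = events
        (out / "events.json").write_text(json.dumps(
            {"site": events.site_id, "variable": events.variable,
             "years": events.years, "severities": events.severities}, indent=2))

    # ---------------------------------------------------------------------- SEA
    @stage("epoch_analysis")
    def _sea():
        events = results["events"]
        rows = []
        corr_rows = []
        ss = np.random.SeedSequence([config.seed, 99])
        child = iter(ss.generate_state(2 * len(results["chronologies"])
                                       + 2 * len(results["greenness"])))
        for label, coll in (("TRI", results["chronologies"]),
                            ("NDVI", results["greenness"])):
            for plot_id in sorted(coll):
                obj = coll[plot_id]
                if label == "TRI":
                    years, vals = obj.years, obj.index
                    resp = pd.Series(vals, index=years)
                else:
                    years, vals = obj.years, obj.residual
                    resp = pd.Series(vals, index=years)
                r = superposed_epoch(years, vals, events, lag=config.sea_lag,
                                     resamples=config.sea_resamples,
                                     seed=int(next(child)) % (2**31),
                                     series_id=f"{label}:{plot_id}")
                rows.append(r.to_frame())
                c = climate_growth_correlations(resp, results["seasonal"])
                c.insert(0, "series_id", f"{label}:{plot_id}")
                corr_rows.append(c)
        _write(pd.concat(rows, ignore_index=True), out / "sea.csv")
        _write(pd.concat(corr_rows, ignore_index=True), out / "correlations.csv")

    # ------------------------------------------------------------------- models
    @stage("response_models")
    def _models():
        events = results["events"]
        sev = results["severity"]
        meta = results["metadata"]
        table_rows = []
        model_rows = []
        for sp in SPECIES:
            plot_ids = meta.loc[meta["species"] == sp, "plot_id"].unique()
            for label, coll, scale in (
                    ("TRI", results["chronologies"], False),
                    ("NDVI", results["greenness"], True)):
                series = {}
                for p in plot_ids:
                    obj = coll[p]
                    vals = obj.index if label == "TRI" else obj.residual
                    series[p] = pd.Series(vals, index=obj.years)
                tab = build_response_table(series, events, sev, meta,
                                           scale_response=scale)
                tab.insert(0, "compartment", label)
                table_rows.append(tab)
                for variant in VARIANTS:
                    fit = model_metrics(fit_random_intercept_lmm(tab, variant),
                                        tab)
                    model_rows.append(dict(
                        species=sp, compartment=label, variant=variant,
                        AIC=fit.aic, r2_marginal=fit.marginal_r2,
                        r2_conditional=fit.conditional_r2,
                        pseudo_r2=fit.pseudo_r2,
                        t_SEV0=fit.t.get("SEV0", np.nan),
                        t_SEV=fit.t.get("SEV", np.nan),
                        p_SEV0=fit.p.get("SEV0", np.nan),
                        p_SEV=fit.p.get("SEV", np.nan),
                        vif_max=float(fit.vif.max()),
                        ranef_p=fit.ranef_p,
                        qq_correlation=fit.qq_correlation,
                        singular=fit.singular))
        results["response_table"] = pd.concat(table_rows, ignore_index=True)
        results["model_table"] = pd.DataFrame(model_rows)
        _write(results["response_table"], out / "response_table.csv")
        _write(results["model_table"], out / "model_table.csv")

        res_rows = []
        for label, coll in (("TRI", results["chronologies"]),
                            ("NDVI", results["greenness"])):
            for plot_id in sorted(coll):
                obj = coll[plot_id]
                vals = obj.index if label == "TRI" else obj.ndvi
                s = pd.Series(vals, index=obj.years)
                for e in events.years:
                    try:
                        rm = resilience_metrics(
                            s, e, plot_id,
                            exclude_years=[y for y in events.years if y != e])
                        res_rows.append(dict(
                            compartment=label, plot_id=plot_id, event_year=e,
                            resistance=rm.resistance, recovery=rm.recovery,
                            resilience=rm.resilience))
                    except ValueError as err:
                        manifest["warnings"].append(str(err))
        results["resilience_table"] = pd.DataFrame(res_rows)
        _write(results["resilience_table"], out / "resilience.csv")

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    results["manifest"] = manifest
    return results
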