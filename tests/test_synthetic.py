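"""Generator determinism, injected-anomaly construction, and the
recoverability of the generated structure through the pipeline stages."""

import numpy as np
import pandas as pd
import pytest

from dryspell.config import SimulationConfig
from dryspell.greenness import (annual_median_composite, extract_plot_series,
                                growing_season_window)
from dryspell.synthetic import (event_multipliers, make_plot_metadata,
                                simulate_climate, simulate_ring_widths,
                                simulate_scenes)
from dryspell.tree_ring import RingWidthSeries, spline_detrend

_MONTH_EDGES = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _no_noise(cfg: SimulationConfig, **extra) -> SimulationConfig:
    d = {**cfg.__dict__, "noise": {"ring_sd": 0.0, "ring_ar": 0.0,
                                   "ndvi_sd": 0.0, "ndvi_ar": 0.0}, **extra}
    return SimulationConfig(**d)


class TestConfigValidation:
    def test_drought_year_outside_range_named(self):
        with pytest.raises(ValueError, match="1950"):
            SimulationConfig(drought_years=(1950, 2003))

    def test_consecutive_drought_years_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            SimulationConfig(drought_years=(2002, 2003))

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="growth_drop"):
            SimulationConfig(growth_drop=1.2)


class TestClimateGenerator:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(seed=5)
        d1, m1 = simulate_climate(cfg)
        d2, m2 = simulate_climate(SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seed_differs(self):
        _, m1 = simulate_climate(SimulationConfig(seed=5))
        _, m2 = simulate_climate(SimulationConfig(seed=6))
        assert not np.allclose(m1["T"], m2["T"])

    def test_monthly_t_is_mean_of_daily(self, climate_tables):
        daily, monthly = climate_tables
        for year in (1985, 2000, 2017):
            d = daily[daily["year"] == year]["T"].to_numpy()
            m = monthly[monthly["year"] == year].sort_values("month")
            for mo in range(12):
                expect = d[_MONTH_EDGES[mo]:_MONTH_EDGES[mo + 1]].mean()
                assert m["T"].iloc[mo] == pytest.approx(expect, abs=1e-9)

    def test_injected_jja_sr_anomaly_meets_configured_sd(self):
        cfg = SimulationConfig(seed=3, sr_anomaly=2.0)
        _, monthly = simulate_climate(cfg)
        jja = monthly[monthly["month"].isin((6, 7, 8))]
        means = jja.groupby("year")["SR"].mean()
        bg = means.drop(index=list(cfg.drought_years))
        z = (means - bg.mean()) / bg.std(ddof=1)
        for y in cfg.drought_years:
            assert z.loc[y] >= 2.0

    def test_injected_jja_sm_depressed(self):
        cfg = SimulationConfig(seed=3, sr_anomaly=2.0)
        _, monthly = simulate_climate(cfg)
        jja = monthly[monthly["month"].isin((6, 7, 8))]
        means = jja.groupby("year")["SM"].mean()
        bg = means.drop(index=list(cfg.drought_years))
        z = (means - bg.mean()) / bg.std(ddof=1)
        for y in cfg.drought_years:
            assert z.loc[y] <= -2.0

    def test_physical_bounds(self, climate_tables):
        _, monthly = climate_tables
        assert (monthly["P"] >= 0).all()
        assert (monthly["SR"] >= 0).all()


class TestRingGenerator:
    def test_same_seed_identical(self, climate_tables, metadata):
        _, monthly = climate_tables
        cfg = SimulationConfig(seed=7)
        a = simulate_ring_widths(monthly, metadata, cfg)
        b = simulate_ring_widths(monthly, metadata, cfg)
        assert all(np.array_equal(x.widths, y.widths) for x, y in zip(a, b))

    def test_widths_positive_and_plot_sampling(self, climate_tables, metadata):
        _, monthly = climate_tables
        rws = simulate_ring_widths(monthly, metadata, SimulationConfig(seed=7))
        assert all((s.widths > 0).all() for s in rws)
        per_plot = pd.Series([s.plot_id for s in rws]).value_counts()
        assert (per_plot >= 26).all()

    def test_age_curve_non_increasing_without_noise(self, climate_tables,
                                                    metadata):
        _, monthly = climate_tables
        cfg = _no_noise(SimulationConfig(seed=7), coupling_sr=0.0,
                        coupling_sm=0.0, growth_drop=0.0,
                        legacy=(0.0, 0.0, 0.0, 0.0))
        rws = simulate_ring_widths(monthly, metadata.head(4), cfg)
        for s in rws:
            assert (np.diff(s.widths) <= 1e-12).all()

    def test_smooth_age_curve_detrends_to_unity(self, climate_tables,
                                                metadata):
        """Noise/coupling/drops off: TRI ~ 1.  Exact (1e-8) for a linear
        trend, which the spline reproduces; within 5e-3 for the default
        exponential, whose curvature leaves a small smoothing bias."""
        _, monthly = climate_tables
        cfg = _no_noise(SimulationConfig(seed=7), coupling_sr=0.0,
                        coupling_sm=0.0, growth_drop=0.0,
                        legacy=(0.0, 0.0, 0.0, 0.0))
        rws = simulate_ring_widths(monthly, metadata.head(4), cfg)
        for s in rws[:5]:
            tri = spline_detrend(s).tri
            assert np.abs(tri - 1.0).max() < 5e-3
        lin = RingWidthSeries("lin", "p", 1985,
                              2.0 - 0.02 * np.arange(33))
        assert np.abs(spline_detrend(lin).tri - 1.0).max() < 1e-8

    def test_nonpositive_age_parameters_rejected(self, climate_tables,
                                                 metadata):
        _, monthly = climate_tables
        with pytest.raises(ValueError, match="age-curve"):
            simulate_ring_widths(monthly, metadata,
                                 SimulationConfig(seed=1, age_tau=-1.0))

    def test_event_multiplier_profile(self):
        cfg = SimulationConfig(seed=0, growth_drop=0.2, legacy=(0.1, 0.05))
        m = event_multipliers(cfg)
        assert m.loc[1994] == pytest.approx(0.8)
        assert m.loc[1995] == pytest.approx(0.9)
        assert m.loc[1996] == pytest.approx(0.95)
        assert m.loc[1990] == pytest.approx(1.0)
        # 2006 sits in the legacy shadow of nothing (2003+3 ends 2005 with
        # a 2-lag legacy), so only its own drop applies
        assert m.loc[2006] == pytest.approx(0.8)


class TestSceneGenerator:
    def test_same_seed_identical(self, climate_tables, metadata):
        daily, _ = climate_tables
        cfg = SimulationConfig(seed=7)
        meta4 = metadata[metadata["plot_id"].isin(
            metadata["plot_id"].unique()[:2])]
        s1, t1, _ = simulate_scenes(daily, meta4, cfg)
        s2, t2, _ = simulate_scenes(daily, meta4, cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_cloud_fraction_binomial(self, climate_tables, metadata):
        daily, _ = climate_tables
        cfg = SimulationConfig(seed=7, cloud_fraction=0.3)
        meta4 = metadata[metadata["plot_id"].isin(
            metadata["plot_id"].unique()[:3])]
        scenes, _, _ = simulate_scenes(daily, meta4, cfg)
        frac = scenes["cloud_flag"].mean()
        assert len(scenes) >= 1000
        assert abs(frac - 0.3) < 0.05

    def test_ndvi_within_bounds(self, climate_tables, metadata):
        daily, _ = climate_tables
        meta4 = metadata[metadata["plot_id"].isin(
            metadata["plot_id"].unique()[:2])]
        scenes, truth, _ = simulate_scenes(daily, meta4,
                                           SimulationConfig(seed=7))
        clear = scenes[scenes["cloud_flag"] == 0]
        v = (clear["nir"] - clear["red"]) / (clear["nir"] + clear["red"])
        assert v.between(-1, 1).all()
        assert truth["ndvi"].dropna().between(-1, 1).all()

    def test_noise_free_cloud_free_recovery_is_exact(self, climate_tables,
                                                     metadata):
        """With no clouds and no observation noise the compositing +
        extraction stages invert the generator exactly."""
        daily, _ = climate_tables
        cfg = _no_noise(SimulationConfig(seed=7), cloud_fraction=0.0)
        plot = metadata["plot_id"].unique()[0]
        meta1 = metadata[metadata["plot_id"] == plot]
        scenes, truth, _ = simulate_scenes(daily, meta1, cfg)
        weights = meta1.set_index("pixel_id")["weight"]
        thr = 9.0 if plot.startswith("PCAB") else 12.0
        cols = {}
        for year in cfg.years:
            win = growing_season_window(daily, year, thr)
            assert win is not None
            cols[year] = annual_median_composite(scenes, win, year)
        annual = extract_plot_series(pd.DataFrame(cols).reindex(weights.index),
                                     weights)
        plot_truth = truth[truth["pixel_id"] == ""].set_index("year")["ndvi"]
        for year in cfg.years:
            assert annual.loc[year] == pytest.approx(plot_truth.loc[year],
                                                     abs=1e-12)
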