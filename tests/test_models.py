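"""Mixed-model estimation, fit metrics, and resilience metric tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dryspell.climate import EventSet
from dryspell.models import (build_response_table, fit_random_intercept_lmm,
                             model_metrics, random_effect_lrt,
                             resilience_metrics, vif)


def make_lmm_data(seed=0, n_groups=4, n_per=100, beta=(0.2, -0.05, -0.03),
                  group_sd=0.02, resid_sd=0.05, center_groups=False):
    """Random-intercept data with known coefficients for SEV0 and SEV.

    ``center_groups`` removes the group means of the errors so that the
    in-sample group variance is exactly zero (the REML boundary case).
    """
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0.0, group_sd, n_groups)
    for g in range(n_groups):
        sev0 = rng.normal(0.0, 1.0, n_per)
        sev = rng.normal(0.0, 1.0, n_per)
        e = b[g] + rng.normal(0.0, resid_sd, n_per)
        if center_groups:
            e = e - e.mean()
        y = beta[0] + beta[1] * sev0 + beta[2] * sev + e
        rows.append(pd.DataFrame({"category": f"G{g}", "SEV0": sev0,
                                  "SEV": sev, "response": y}))
    return pd.concat(rows, ignore_index=True)


class TestLmmFit:
    def test_zero_group_variance_collapses_to_ols(self):
        tab = make_lmm_data(seed=1, group_sd=0.0, center_groups=True)
        fit = fit_random_intercept_lmm(tab, "full")
        X = np.column_stack([np.ones(len(tab)), tab["SEV0"], tab["SEV"]])
        ols, *_ = np.linalg.lstsq(X, tab["response"].to_numpy(), rcond=None)
        assert np.max(np.abs(fit.params.to_numpy() - ols)) < 1e-6
        assert fit.group_var <= 1e-6

    def test_balanced_two_group_matches_anova_closed_form(self):
        rng = np.random.default_rng(3)
        n_per, delta = 50, 1.0
        e = rng.normal(0.0, 0.3, 2 * n_per)
        y = np.r_[e[:n_per] - delta / 2, e[n_per:] + delta / 2]
        tab = pd.DataFrame({"category": ["A"] * n_per + ["B"] * n_per,
                            "response": y})
        fit = fit_random_intercept_lmm(tab, variant=())   # intercept only
        # closed-form one-way REML: sigma_e^2 = MSW, sigma_b^2 = (MSB-MSW)/n
        ya, yb = y[:n_per], y[n_per:]
        msw = (np.sum((ya - ya.mean())**2) + np.sum((yb - yb.mean())**2)) \
            / (2 * n_per - 2)
        msb = n_per * ((ya.mean() - y.mean())**2 + (yb.mean() - y.mean())**2)
        expect_b = (msb - msw) / n_per
        assert fit.resid_var == pytest.approx(msw, rel=1e-4)
        assert fit.group_var == pytest.approx(expect_b, rel=1e-3)

    def test_agrees_with_statsmodels_reml(self):
        """Independent cross-check against the statsmodels MixedLM fitter."""
        import statsmodels.formula.api as smf
        tab = make_lmm_data(seed=5, group_sd=0.05, n_per=60)
        fit = fit_random_intercept_lmm(tab, "full")
        sm_fit = smf.mixedlm("response ~ SEV0 + SEV", tab,
                             groups=tab["category"]).fit(reml=True)
        assert np.allclose(fit.params.to_numpy(),
                           sm_fit.fe_params.to_numpy(), atol=1e-5)
        assert fit.resid_var == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.group_var == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                              rel=1e-2)
        assert np.allclose(fit.se.to_numpy(), sm_fit.bse_fe.to_numpy(),
                           rtol=1e-3)

    def test_sign_recovery_of_negative_effects(self):
        neg = 0
        for seed in range(20):
            tab = make_lmm_data(seed=seed)
            fit = fit_random_intercept_lmm(tab, "full")
            neg += (fit.t["SEV0"] < 0) and (fit.t["SEV"] < 0)
        assert neg >= 19

    def test_single_group_rejected(self):
        tab = make_lmm_data(n_groups=1)
        with pytest.raises(ValueError, match="group"):
            fit_random_intercept_lmm(tab, "full")

    def test_collinear_design_rejected(self):
        tab = make_lmm_data(seed=2)
        tab["SEV"] = 2.0 * tab["SEV0"]
        with pytest.raises(ValueError, match="rank"):
            fit_random_intercept_lmm(tab, "full")

    def test_aic_prefers_generating_variant(self):
        hits = 0
        for seed in range(25):
            tab = make_lmm_data(seed=seed, beta=(0.2, -0.08, 0.0))
            aics = {v: fit_random_intercept_lmm(tab, v).aic
                    for v in ("full", "without_SEV0", "without_SEV")}
            hits += min(aics, key=aics.get) == "without_SEV"
        assert hits >= 20


class TestModelMetrics:
    def test_zero_group_variance_equalizes_r2(self):
        tab = make_lmm_data(seed=1, group_sd=0.0, center_groups=True)
        fit = model_metrics(fit_random_intercept_lmm(tab, "full"), tab)
        assert fit.marginal_r2 == pytest.approx(fit.conditional_r2, abs=1e-8)

    def test_noise_free_linear_data_r2_one(self):
        tab = make_lmm_data(seed=2, group_sd=0.0, resid_sd=1e-8)
        fit = model_metrics(fit_random_intercept_lmm(tab, "full"), tab)
        assert fit.marginal_r2 == pytest.approx(1.0, abs=1e-4)
        assert fit.conditional_r2 == pytest.approx(1.0, abs=1e-4)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-6)

    def test_known_variance_shares_recovered(self):
        # fixed 0.3, group 0.2, residual 0.5 of the total variance
        tab = make_lmm_data(seed=4, n_groups=20, n_per=100,
                            beta=(0.0, np.sqrt(0.15), np.sqrt(0.15)),
                            group_sd=np.sqrt(0.2), resid_sd=np.sqrt(0.5))
        fit = model_metrics(fit_random_intercept_lmm(tab, "full"), tab)
        assert fit.marginal_r2 == pytest.approx(0.3, abs=0.05)
        assert fit.conditional_r2 == pytest.approx(0.5, abs=0.05)

    def test_omitting_strong_sev0_reduces_marginal_r2(self):
        for seed in range(5):
            tab = make_lmm_data(seed=seed, beta=(0.2, -0.10, -0.02))
            full = model_metrics(fit_random_intercept_lmm(tab, "full"), tab)
            drop = model_metrics(
                fit_random_intercept_lmm(tab, "without_SEV0"), tab)
            assert drop.marginal_r2 < full.marginal_r2

    def test_conditional_never_below_marginal(self):
        for seed in range(5):
            tab = make_lmm_data(seed=seed, group_sd=0.05)
            fit = model_metrics(fit_random_intercept_lmm(tab, "full"), tab)
            assert fit.conditional_r2 >= fit.marginal_r2 - 1e-12
            assert fit.qq_correlation > 0.98


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        out = vif(pd.DataFrame({"a": np.tile([1., -1.], 20),
                                "b": np.repeat([1., -1.], 20)}))
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_half_correlated_pair_closed_form(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(20000, 2))
        a = z[:, 0]
        b = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1.3333, abs=0.02)
        assert out["b"] == pytest.approx(1.3333, abs=0.02)

    def test_duplicated_column_infinite(self):
        a = np.random.default_rng(1).normal(size=50)
        out = vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(out).all()

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(2)
        out = vif(pd.DataFrame(rng.normal(size=(200, 3)),
                               columns=list("abc")))
        assert (out >= 1.0 - 1e-12).all()


class TestRandomEffectLrt:
    def test_statistic_non_negative(self):
        for seed in range(5):
            tab = make_lmm_data(seed=seed, group_sd=0.0)
            stat, p = random_effect_lrt(tab, "full")
            assert stat >= 0.0
            assert 0.0 <= p <= 1.0

    def test_null_rarely_rejects(self):
        rejects = sum(random_effect_lrt(make_lmm_data(seed=s, group_sd=0.0),
                                        "full")[1] < 0.05
                      for s in range(30))
        assert rejects <= 4

    def test_strong_group_structure_detected(self):
        hits = sum(random_effect_lrt(
            make_lmm_data(seed=s, group_sd=0.05, resid_sd=0.05),
            "full")[1] < 0.01 for s in range(20))
        assert hits >= 18


class TestResponseTable:
    def _series(self, plot_ids, years=range(1985, 2018)):
        years = list(years)
        return {p: pd.Series(1.0 + 0.01 * i, index=years)
                for i, p in enumerate(plot_ids)}

    def _meta(self, plot_ids):
        return pd.DataFrame({"plot_id": plot_ids, "species": "PCAB",
                             "category": ["SS", "NS", "PL", "VA"]
                             * (len(plot_ids) // 4)})

    def _severity(self):
        rng = np.random.default_rng(9)
        return pd.Series(rng.normal(size=33), index=range(1985, 2018))

    def test_complete_design_row_count(self):
        plots = [f"P{i}" for i in range(20)]
        ev = EventSet("s", "SR", [1994, 2003, 2006, 2010], [1, 1, 1, 1])
        tab = build_response_table(self._series(plots), ev, self._severity(),
                                   self._meta(plots))
        assert len(tab) == 20 * 4 * 5

    def test_event_at_series_end_keeps_only_lag0(self):
        plots = ["P0", "P1", "P2", "P3"]
        ev = EventSet("s", "SR", [2017], [1.0])
        tab = build_response_table(self._series(plots), ev, self._severity(),
                                   self._meta(plots))
        assert set(tab["lag"]) == {0}

    def test_lag0_sev_equals_sev0(self):
        plots = ["P0", "P1", "P2", "P3"]
        ev = EventSet("s", "SR", [1994, 2003], [1.0, 1.0])
        tab = build_response_table(self._series(plots), ev, self._severity(),
                                   self._meta(plots))
        lag0 = tab[tab["lag"] == 0]
        assert np.allclose(lag0["SEV"], lag0["SEV0"])

    def test_scaled_response_standardized_per_plot(self):
        plots = ["P0", "P1", "P2", "P3"]
        rng = np.random.default_rng(4)
        series = {p: pd.Series(rng.normal(0.7, 0.1, 33),
                               index=range(1985, 2018)) for p in plots}
        ev = EventSet("s", "SR", [1994, 2003], [1.0, 1.0])
        tab = build_response_table(series, ev, self._severity(),
                                   self._meta(plots), scale_response=True)
        for p in plots:
            z = (series[p] - series[p].mean()) / series[p].std(ddof=1)
            sub = tab[tab["plot_id"] == p]
            assert np.allclose(sub["response"],
                               z.loc[sub["year"]].to_numpy(), atol=1e-12)


class TestResilience:
    def test_worked_toy_values(self):
        years = range(1990, 2001)
        vals = [1.0] * 11
        s = pd.Series(vals, index=years, dtype=float)
        s.loc[1995] = 0.5
        s.loc[[1996, 1997, 1998]] = 0.75
        m = resilience_metrics(s, 1995)
        assert m.resistance == pytest.approx(0.5)
        assert m.recovery == pytest.approx(1.5)
        assert m.resilience == pytest.approx(0.75)

    def test_flat_series_all_ones(self):
        s = pd.Series(1.0, index=range(1990, 2001))
        m = resilience_metrics(s, 1995)
        assert (m.resistance, m.recovery, m.resilience) == (1.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0.05, max_value=3.0), min_size=7,
                    max_size=7))
    def test_identity_resilience_is_product(self, vals):
        s = pd.Series(vals, index=range(1990, 1997))
        m = resilience_metrics(s, 1993)
        assert m.resilience == pytest.approx(m.resistance * m.recovery,
                                             abs=1e-12)

    def test_other_events_excluded_from_windows(self):
        s = pd.Series(1.0, index=range(1990, 2001))
        s.loc[1993] = 0.1    # another event inside the pre window
        s.loc[1995] = 0.5
        m = resilience_metrics(s, 1995, exclude_years=[1993])
        assert m.resistance == pytest.approx(0.5)
        assert m.pre_years == 2

    def test_zero_event_value_rejected(self):
        s = pd.Series(1.0, index=range(1990, 2001))
        s.loc[1995] = 0.0
        with pytest.raises(ValueError):
            resilience_metrics(s, 1995)
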