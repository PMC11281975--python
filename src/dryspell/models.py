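"""Mixed-effects response models and resilience metrics.

The model is a Gaussian random-intercept LMM: response (TRI or per-plot
scaled NDVI residual) in the event year and the four following years,
regressed on the event-year severity (SEV0) and the row-year severity
(SEV), with the plot category (SS/NS/PL/VA) as a random intercept.

Estimation is REML, profiled to a one-dimensional optimization over the
variance ratio lambda = sigma_group^2 / sigma_resid^2: for fixed lambda the
GLS fixed effects and the residual variance have closed forms (the grouped
covariance inverts by Sherman-Morrison), so the profiled REML criterion is
maximized with a scalar optimizer.  The lambda = 0 boundary is checked
explicitly, giving an exact OLS collapse when the group variance vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .climate import EventSet

VARIANTS = ("full", "without_SEV0", "without_SEV")
_VARIANT_COLS = {"full": ("SEV0", "SEV"),
                 "without_SEV0": ("SEV",),
                 "without_SEV": ("SEV0",)}


def _variant_cols(variant) -> tuple[str, ...]:
    """Named variant -> severity columns; a sequence passes through (an
    empty one gives the intercept-only model)."""
    if isinstance(variant, str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        return _VARIANT_COLS[variant]
    return tuple(variant)


@dataclass
class LMMFit:
    variant: str | tuple
    fixed_cols: tuple
    params: pd.Series             # fixed effects (incl. intercept)
    se: pd.Series
    t: pd.Series
    p: pd.Series
    group_var: float              # random-intercept variance
    resid_var: float
    loglik: float                 # REML log-likelihood
    aic: float
    n: int
    groups: list[str]
    group_effects: pd.Series      # BLUPs
    fitted_fixed: np.ndarray
    fitted: np.ndarray            # fixed + group effects
    residuals: np.ndarray
    singular: bool
    marginal_r2: float = np.nan
    conditional_r2: float = np.nan
    pseudo_r2: float = np.nan
    vif: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    ranef_lrt: float = np.nan
    ranef_p: float = np.nan
    qq_correlation: float = np.nan


@dataclass
class ResilienceMetrics:
    plot_id: str
    event_year: int
    resistance: float
    recovery: float
    resilience: float
    pre_years: int
    post_years: int


# ---------------------------------------------------------------------------
# response table
# ---------------------------------------------------------------------------

def build_response_table(series: dict[str, pd.Series], events: EventSet,
                         severity: pd.Series, metadata: pd.DataFrame,
                         n_lags: int = 4, scale_response: bool = False,
                         sev_zero_at_lag0: bool = False) -> pd.DataFrame:
    """Stack plot responses at lags 0..n_lags after each event.

    ``series`` maps plot_id -> annual response series (index = year);
    ``severity`` is the annual severity-anomaly series whose event-year
    value becomes SEV0 and row-year value SEV.  With ``scale_response``
    each plot's series is standardized (mean 0, SD 1) first — used for the
    NDVI residuals so both compartments are on comparable scales.  Rows
    whose lag year leaves the series support are omitted.
    """
    meta = metadata.drop_duplicates("plot_id").set_index("plot_id")
    rows = []
    for plot_id, s in series.items():
        s = s.dropna()
        if scale_response:
            s = (s - s.mean()) / s.std(ddof=1)
        for e in events.years:
            for lag in range(n_lags + 1):
                y = e + lag
                if y not in s.index or y not in severity.index:
                    continue
                sev = float(severity.loc[y])
                if lag == 0 and sev_zero_at_lag0:
                    sev = 0.0
                rows.append(dict(
                    plot_id=plot_id,
                    species=meta.loc[plot_id, "species"],
                    category=meta.loc[plot_id, "category"],
                    event_year=e, lag=lag, year=y,
                    response=float(s.loc[y]),
                    SEV0=float(severity.loc[e]), SEV=sev))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiled REML for the random-intercept model
# ---------------------------------------------------------------------------

def _profile_reml(y: np.ndarray, X: np.ndarray, gidx: np.ndarray,
                  n_groups: int, lam: float):
    """Profiled REML log-likelihood at variance ratio lam, plus GLS pieces.

    V0 = I + lam * Z Z', inverted per group by Sherman-Morrison.
    """
    n, p = X.shape
    counts = np.bincount(gidx, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * counts)            # per-group SM factor
    Xg = np.zeros((n_groups, p))
    yg = np.zeros(n_groups)
    for j in range(p):
        Xg[:, j] = np.bincount(gidx, weights=X[:, j], minlength=n_groups)
    yg = np.bincount(gidx, weights=y, minlength=n_groups)
    XtVX = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    XtVy = X.T @ y - (Xg * shrink[:, None]).T @ yg
    ytVy = y @ y - np.sum(shrink * yg**2)
    beta = np.linalg.solve(XtVX, XtVy)
    q = ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    q = max(q, 1e-300)
    sigma2 = q / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    logdet_v0 = float(np.sum(np.log1p(lam * counts)))
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
                 + logdet_v0 + logdet_xvx)
    return ll, beta, sigma2, XtVX, counts, yg, Xg


def fit_random_intercept_lmm(table: pd.DataFrame, variant: str = "full",
                             response_col: str = "response",
                             group_col: str = "category") -> LMMFit:
    """REML fit of response ~ severities + (1 | group)."""
    cols = _variant_cols(variant)
    groups = sorted(table[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("random intercept needs >=2 groups")
    gmap = {g: i for i, g in enumerate(groups)}
    gidx = table[group_col].astype(str).map(gmap).to_numpy()
    y = table[response_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y))] + [table[c].to_numpy(dtype=float)
                                             for c in cols])
    names = ["Intercept", *cols]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    def neg(loglam):
        return -_profile_reml(y, X, gidx, len(groups), 10.0 ** loglam)[0]

    res = optimize.minimize_scalar(neg, bounds=(-8.0, 6.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = 10.0 ** res.x
    ll_hat = -res.fun
    ll0 = _profile_reml(y, X, gidx, len(groups), 0.0)[0]
    singular = False
    if ll0 >= ll_hat - 1e-10:
        lam, ll_hat, singular = 0.0, ll0, True
    ll, beta, sigma2, XtVX, counts, yg, Xg = _profile_reml(
        y, X, gidx, len(groups), lam)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    # BLUPs: b_i = lam * sum(resid_i) / (1 + lam * n_i)
    resid_fix = y - X @ beta
    rsum = np.bincount(gidx, weights=resid_fix, minlength=len(groups))
    blup = lam * rsum / (1.0 + lam * counts)
    fitted_fixed = X @ beta
    fitted = fitted_fixed + blup[gidx]
    n, p = X.shape
    k = p + 2   # fixed effects + group variance + residual variance
    return LMMFit(
        variant=variant,
        fixed_cols=cols,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        t=pd.Series(tvals, index=names),
        p=pd.Series(pvals, index=names),
        group_var=lam * sigma2,
        resid_var=sigma2,
        loglik=float(ll),
        aic=float(-2 * ll + 2 * k),
        n=n, groups=groups,
        group_effects=pd.Series(blup, index=groups),
        fitted_fixed=fitted_fixed, fitted=fitted,
        residuals=y - fitted, singular=singular)


def _fixed_only_reml_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """REML log-likelihood of the linear model without random effects.

    Same criterion as the mixed fit at lambda = 0, so the two are directly
    comparable in a likelihood-ratio test.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    sigma2 = rss / (n - p)
    _, logdet = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet)


def random_effect_lrt(table: pd.DataFrame, variant: str = "full",
                      response_col: str = "response",
                      group_col: str = "category") -> tuple[float, float]:
    """ranova-style REML likelihood-ratio test of the random intercept.

    Statistic = 2 * (REML loglik with the intercept - without), floored at
    0; reference distribution chi-square(1).
    """
    fit = fit_random_intercept_lmm(table, variant, response_col, group_col)
    cols = _variant_cols(variant)
    y = table[response_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y))] + [table[c].to_numpy(dtype=float)
                                             for c in cols])
    ll0 = _fixed_only_reml_loglik(y, X)
    stat = max(0.0, 2.0 * (fit.loglik - ll0))
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1 / (1 - R2) of each predictor on the rest.

    Auxiliary regressions include an intercept.  Perfect collinearity comes
    back as +inf.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs >=2 predictors")
    X = design.to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column")
    out = {}
    for j, name in enumerate(cols):
        target = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, target, rcond=None)
        rss = np.sum((target - others @ beta) ** 2)
        tss = np.sum((target - target.mean()) ** 2)
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def model_metrics(fit: LMMFit, table: pd.DataFrame,
                  response_col: str = "response") -> LMMFit:
    """Attach Nakagawa R², pseudo-R², VIF, random-effect LRT and a
    qq-correlation normality summary to a fit."""
    y = table[response_col].to_numpy(dtype=float)
    var_fix = float(np.var(fit.fitted_fixed))
    denom = var_fix + fit.group_var + fit.resid_var
    if denom <= 0:
        raise ValueError("zero total variance")
    fit.marginal_r2 = var_fix / denom
    fit.conditional_r2 = (var_fix + fit.group_var) / denom
    if np.ptp(fit.fitted) == 0 or np.ptp(y) == 0:
        fit.pseudo_r2 = np.nan
    else:
        fit.pseudo_r2 = float(np.corrcoef(y, fit.fitted)[0, 1] ** 2)
    cols = list(fit.fixed_cols)
    if len(cols) >= 2:
        fit.vif = vif(table[cols])
    else:
        fit.vif = pd.Series({c: 1.0 for c in cols}, name="VIF",
                            dtype=float)
    fit.ranef_lrt, fit.ranef_p = random_effect_lrt(
        table, fit.variant, response_col)
    r = np.sort(fit.residuals)
    if np.ptp(r) > 0:
        q = stats.norm.ppf((np.arange(1, len(r) + 1) - 0.5) / len(r))
        fit.qq_correlation = float(np.corrcoef(r, q)[0, 1])
    return fit


# ---------------------------------------------------------------------------
# resilience metrics (Lloret-type ratios)
# ---------------------------------------------------------------------------

def resilience_metrics(series: pd.Series, event_year: int, plot_id: str = "",
                       pre_years: int = 3, post_years: int = 3,
                       exclude_years=()) -> ResilienceMetrics:
    """Resistance, recovery and resilience around one event.

    resistance = event / pre-window mean; recovery = post-window mean /
    event; resilience = post / pre (== resistance * recovery).  Other event
    years can be excluded from the windows.
    """
    s = series.dropna()
    if event_year not in s.index:
        raise ValueError(f"event year {event_year} not in series")
    pre = [y for y in range(event_year - pre_years, event_year)
           if y in s.index and y not in exclude_years]
    post = [y for y in range(event_year + 1, event_year + post_years + 1)
            if y in s.index and y not in exclude_years]
    if not pre or not post:
        raise ValueError(f"event {event_year}: empty pre or post window")
    ev = float(s.loc[event_year])
    pre_m = float(s.loc[pre].mean())
    post_m = float(s.loc[post].mean())
    if ev == 0 or pre_m == 0:
        raise ValueError("zero event value or pre-window mean")
    return ResilienceMetrics(plot_id, event_year,
                             resistance=ev / pre_m,
                             recovery=post_m / ev,
                             resilience=post_m / pre_m,
                             pre_years=len(pre), post_years=len(post))
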