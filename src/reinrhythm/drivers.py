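"""Environmental drivers of diel rhythm power.

A random-intercept linear mixed model relates the natural log of the mean
significant 21-27 h normalized power per 15-day window to three
window-averaged zeitgeber covariates: daily variance of direct maximum
solar radiation, daily variance of collar (ambient) temperature, and the
fitted NDVI curve.  Individual identity enters as a random intercept to
absorb repeated measures; predictors and response are z-scored over the
analysis sample, so the reported coefficients are standardized betas.
Per-predictor Wald F statistics use numerator df 1 and denominator df
n_rows - 3 - 1 (a pinned containment-style rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

log = logging.getLogger("reinrhythm")

PREDICTORS = ("sun_var", "tcollar_var", "ndvi_mean")


@dataclass
class DriverFit:
    betas: dict  # standardized coefficient per predictor
    F_stats: dict  # per-predictor Wald F with (1, denom_df)
    p_values: dict
    denom_df: int
    var_random: float  # between-individual intercept variance (z-scale)
    var_resid: float
    n_rows: int
    converged: bool = True


def assemble_drivers(
    power_windows: dict,
    solar_days: pd.DataFrame,
    tcollar_daily: dict,
    ndvi_fit,
) -> pd.DataFrame:
    """One row per individual x 15-day window with significant diel power.

    ``power_windows`` maps individual_id -> output of
    :func:`reinrhythm.rhythms.windowed_power`; ``solar_days`` is the per-day
    solar table (columns date, radiation_variance); ``tcollar_daily`` maps
    individual_id -> daily-summary frame (date, variance) of collar
    temperature; ``ndvi_fit`` is the fitted NDVI curve.  Predictors are
    averaged over each window's days; the response is the natural log of
    the window's mean significant power.  Windows with absent power are
    skipped; non-positive powers are dropped with a warning.
    """
    sol = solar_days.set_index(pd.DatetimeIndex(solar_days["date"]))
    rows = []
    for ind, windows in power_windows.items():
        tc = tcollar_daily.get(ind)
        tc_idx = None
        if tc is not None:
            tc = pd.DataFrame(tc)
            tc_idx = tc.set_index(pd.DatetimeIndex(tc["date"]))
        for win, power in windows:
            if power is None:
                continue
            if power <= 0:
                log.warning("assemble_drivers: non-positive power in %s; dropped", win.label)
                continue
            days = pd.date_range(win.start.floor("D"), win.end, freq="D", inclusive="left")
            sun = sol.reindex(days)["radiation_variance"].dropna()
            ndvi = ndvi_fit.predict(days.dayofyear.to_numpy(dtype=float))
            row = {
                "individual_id": ind,
                "window_start": win.start,
                "log_power": float(np.log(power)),
                "sun_var": float(sun.mean()) if len(sun) else np.nan,
                "ndvi_mean": float(np.mean(ndvi)),
            }
            if tc_idx is not None:
                tv = tc_idx.reindex(days)["variance"].dropna()
                row["tcollar_var"] = float(tv.mean()) if len(tv) else np.nan
            else:
                row["tcollar_var"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.dropna(subset=["sun_var", "tcollar_var", "ndvi_mean", "log_power"])
    return df.reset_index(drop=True)


def fit_mixed_model(
    rows: pd.DataFrame,
    predictors=PREDICTORS,
    response: str = "log_power",
    group: str = "individual_id",
) -> DriverFit:
    """REML random-intercept fit on z-scored response and predictors.

    Needs >= 2 individuals and >= 10 rows.  A singular fit (random
    intercept variance at the boundary) is returned with var_random = 0
    and a warning, not raised.
    """
    rows = pd.DataFrame(rows)
    if rows[group].nunique() < 2 or len(rows) < 10:
        raise ValueError("need >= 2 individuals and >= 10 rows")
    z = {}
    for col in (response, *predictors):
        v = rows[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"predictor {col} has zero variance")
        z[col] = (v - v.mean()) / sd
    endog = z[response]
    exog = sm.add_constant(np.column_stack([z[p] for p in predictors]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=rows[group].to_numpy())
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            log.warning("MixedLM failed (%s); refitting with variance near zero", exc)
            res = model.fit(reml=True, method="cg")
            converged = False
    var_random = float(np.squeeze(np.asarray(res.cov_re)))
    if var_random < 1e-10:
        log.warning("fit_mixed_model: random-intercept variance at boundary; reporting 0")
        var_random = 0.0
    n = len(rows)
    denom_df = n - len(predictors) - 1
    betas, Fs, ps = {}, {}, {}
    for i, p in enumerate(predictors, start=1):
        beta = float(res.params[i])
        se = float(res.bse[i])
        F = (beta / se) ** 2 if se > 0 else np.inf
        betas[p] = beta
        Fs[p] = float(F)
        ps[p] = float(stats.f.sf(F, 1, denom_df))
    return DriverFit(
        betas=betas,
        F_stats=Fs,
        p_values=ps,
        denom_df=denom_df,
        var_random=var_random,
        var_resid=float(res.scale),
        n_rows=n,
        converged=converged,
    )


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def report_table(fit: DriverFit) -> pd.DataFrame:
    """Predictor-per-row summary table: beta, F(1, denom_df), p."""
    rows = []
    for p in fit.betas:
        rows.append(
            {
                "predictor": p,
                "beta": round(fit.betas[p], 3),
                f"F(1,{fit.denom_df})": round(fit.F_stats[p], 2),
                "p": _fmt_p(fit.p_values[p]),
            }
        )
    return pd.DataFrame(rows)
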