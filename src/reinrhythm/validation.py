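"""End-to-end validation experiments on synthetic telemetry.

Each function here runs one self-contained recovery or calibration
experiment through the public pipeline — generating its own inputs under
the default study conditions, executing the relevant stages, and measuring
the result.  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes are documented in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import drivers, qc, rhythms, seasonal, simulate, solar
from .core import TelemetrySeries, daily_frame, daily_stats
from .qc import BeatWindow


def hr_ceiling() -> float:
    """Heart-rate ceiling realised by the sensor dead time.

    A window of back-to-back 0.5-s inter-beat intervals must yield a modal
    rate of exactly 60/0.5 = 120 bpm.
    """
    w = BeatWindow(
        start=pd.Timestamp("2013-01-01"),
        intervals=np.full(360, qc.SENSOR_DEAD_TIME_S),
    )
    return float(qc.modal_heart_rate(w))


def light_season_days(year: int = 2013, latitude: float = solar.SITE_LAT_NORTH):
    """Day-of-year of first and last continual-civil-daylight day."""
    first_ll, last_ll, _, _ = solar.find_light_season_bounds(year, latitude)
    return int(first_ll.dayofyear), int(last_ll.dayofyear)


def ls_oracle_max_rel_error(seed: int = 0, n_freqs: int = 5) -> float:
    """Worst relative disagreement between the periodogram and the
    brute-force least-squares sinusoid oracle at random frequencies."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range("2013-02-01", periods=7200, freq="180s")
    keep = rng.random(7200) < 0.7
    hours = np.arange(7200)[keep] * 0.05
    y = 0.3 * np.cos(2 * np.pi * hours / 23.0) + rng.normal(0, 1, int(keep.sum()))
    s = TelemetrySeries("activity", ts[keep], (y - y.min()) / (y.max() - y.min()))
    t = s.hours_since()
    yc = s.values - s.values.mean()
    worst = 0.0
    for period in rng.uniform(0.6, 29.0, n_freqs):
        pg = rhythms.lomb_scargle(s, band=(period, period * 1.5), M=4)
        w = 2 * np.pi / pg.periods[-1]
        X = np.column_stack([np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        oracle = ((yc ** 2).sum() - ((yc - X @ beta) ** 2).sum()) / (2.0 * yc.var())
        worst = max(worst, abs(pg.powers[-1] / oracle - 1.0))
    return float(worst)


def type_one_error(seed: int = 0, n_windows: int = 1000, alpha: float = 0.05) -> float:
    """Empirical type-I rate of the windowed 21-27 h min-p test on white noise."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range("2013-02-01", periods=7200, freq="180s")
    hits = 0
    for _ in range(n_windows):
        s = TelemetrySeries("activity", ts, rng.normal(0.5, 0.1, 7200))
        pg = rhythms.lomb_scargle(rhythms.detrend(s), band=rhythms.DIEL_BAND_H)
        hits += bool(rhythms.extract_peaks(pg, alpha=alpha))
    return hits / n_windows


def tau_recovery(seed: int = 0, taus=(23.2, 24.0, 25.5), reps: int = 100) -> dict:
    """Fraction of 15-day windows whose top diel peak lands within one grid
    step of the true period, at the generator's default rumen-temperature
    signal-to-noise and record dropout."""
    cfg = simulate.default_paper_config()
    amp = cfg.diel_amp["t_rumen"]
    noise = cfg.noise_sd["t_rumen"]
    dropout = cfg.record_dropout_frac
    rng = np.random.default_rng(seed)
    ts = pd.date_range("2013-02-01", periods=7200, freq="180s")
    hours_all = np.arange(7200) * 0.05
    out = {}
    for tau in taus:
        hit = 0
        for _ in range(reps):
            keep = rng.random(7200) >= dropout
            hours = hours_all[keep]
            y = 38.3 + amp * np.cos(2 * np.pi * hours / tau + rng.uniform(0, 2 * np.pi))
            y = y + rng.normal(0, noise, len(hours))
            s = TelemetrySeries("t_rumen", ts[keep], y)
            pg = rhythms.lomb_scargle(rhythms.detrend(s), band=rhythms.DIEL_BAND_H)
            top = pg.periods[np.argmax(pg.powers)]
            step = np.abs(np.diff(pg.periods)).max()
            hit += abs(top - tau) <= step
        out[tau] = hit / reps
    return out


def qc_recovery(seed: int = 0, n_days: int = 60) -> dict:
    """Full QC pipeline against ground truth on one simulated deployment.

    Returns the mean absolute error of the stationary heart rate (bpm), the
    fraction of injected +50 bpm contamination spikes removed, and the
    fraction of labelled drinking-dip records removed by the 0.25 degC
    filter.
    """
    cfg = simulate.default_paper_config(seed=seed)
    cfg.individuals = 1
    start = pd.Timestamp("2012-11-15")
    cfg.start, cfg.end = str(start.date()), str((start + pd.Timedelta(days=n_days)).date())
    res = simulate.generate(cfg)
    ind = "sim1"
    hr, _ = qc.stationary_heart_rate(res.beats[ind], res.series[ind]["activity"])
    truth = res.truth.per_individual[ind]["true_hr"].set_index("start")["true_bpm"]
    mae = float(np.abs(hr.values - truth.reindex(hr.timestamps).to_numpy()).mean())

    kept = set(hr.timestamps)
    spikes = list(res.truth.per_individual[ind]["spike_starts"])
    spike_removed = sum(1 for s in spikes if s not in kept) / len(spikes)

    tr = res.series[ind]["t_rumen"]
    filt = qc.filter_trumen(tr)
    dips = pd.DatetimeIndex(res.truth.per_individual[ind]["drink_records"])
    present = dips.intersection(tr.timestamps)
    dip_removed = 1.0 - len(dips.intersection(filt.timestamps)) / len(present)
    return {
        "hr_mae_bpm": mae,
        "spike_removed_frac": float(spike_removed),
        "dip_removed_frac": float(dip_removed),
    }


def annual_ci_coverage(seed: int = 0, reps: int = 100, n_boot: int = 500,
                       noise_sd: float = 3.0) -> dict:
    """Bootstrap-CI coverage of the annual-peak parameters.

    Daily heart-rate means are simulated from the default profile with the
    stated daily noise; nominal 95% intervals for baseline and height are
    scored against truth over ``reps`` replicates.
    """
    cfg = simulate.default_paper_config()
    b, H, tp, w = cfg.annual["hr"]
    days = pd.date_range("2013-01-01", periods=365, freq="D")
    mu = seasonal.baseline_cosine_predict(days.dayofyear.to_numpy(dtype=float), b, H, tp, w)
    rng = np.random.default_rng(seed)
    cover_b = cover_h = 0
    for rep in range(reps):
        df = pd.DataFrame({"date": days, "mean": mu + rng.normal(0, noise_sd, 365)})
        fit = seasonal.fit_baseline_cosine(df, n_boot=n_boot, seed=int(rng.integers(2 ** 31)))
        cover_b += fit.ci["b"][0] <= b <= fit.ci["b"][1]
        cover_h += fit.ci["H"][0] <= H <= fit.ci["H"][1]
    return {"coverage_b": cover_b / reps, "coverage_H": cover_h / reps}


def noiseless_pct_increase() -> float:
    """Percent summer increase of stationary heart rate recovered from a
    noise-free realisation of the default annual profile."""
    cfg = simulate.default_paper_config()
    b, H, tp, w = cfg.annual["hr"]
    days = pd.date_range("2013-01-01", periods=365, freq="D")
    df = pd.DataFrame(
        {"date": days,
         "mean": seasonal.baseline_cosine_predict(days.dayofyear.to_numpy(dtype=float), b, H, tp, w)}
    )
    fit = seasonal.fit_baseline_cosine(df, n_boot=0)
    return float(seasonal.annual_summary(fit).pct_increase)


def _driver_rows(rng, n=200, betas=(0.5, 0.0, -0.7), sd_u=0.3, sd_e=0.5, n_ind=5):
    g = np.repeat(np.arange(n_ind), n // n_ind)
    X = rng.normal(size=(n, 3))
    y = X @ np.array(betas) + rng.normal(0, sd_u, n_ind)[g] + rng.normal(0, sd_e, n)
    return pd.DataFrame(
        {"individual_id": g, "log_power": y,
         "sun_var": X[:, 0], "tcollar_var": X[:, 1], "ndvi_mean": X[:, 2]}
    )


def driver_beta_recovery(seed: int = 0, reps: int = 100) -> dict:
    """Median absolute error of the standardized mixed-model coefficients
    over replicated row simulations with known effects (0.5, 0, -0.7)."""
    rng = np.random.default_rng(seed)
    betas = (0.5, 0.0, -0.7)
    errs = []
    for _ in range(reps):
        fit = drivers.fit_mixed_model(_driver_rows(rng, betas=betas))
        errs.append([fit.betas[p] - b for p, b in zip(drivers.PREDICTORS, betas)])
    med = np.median(np.abs(errs), axis=0)
    return dict(zip(drivers.PREDICTORS, (float(m) for m in med)))


def closed_loop(seed: int = 0) -> dict:
    """Full-pipeline run on the default study year.

    Simulates three animals, detects per-season diel peaks in activity,
    classifies entrained/free-running per photic season, and fits the
    mixed model of windowed log power against the zeitgeber covariates.
    Returns the season-label accuracy (DD expected free-running, LD/LL
    expected entrained) and the fitted driver coefficients.
    """
    cfg = simulate.default_paper_config(seed=seed)
    res = simulate.generate(cfg, channels=("activity", "t_collar"))
    ndvi, _ = simulate.generate_ndvi(cfg)
    nfit = seasonal.fit_ndvi_curve(ndvi, n_boot=0)
    sol = solar.day_table(cfg.start, cfg.end, cfg.latitude, cfg.longitude, grid_step=600)

    # per-season entrainment labels from the first animal's activity
    act = res.series["sim1"]["activity"]
    peaks = rhythms.season_peaks(act, res.truth.seasons)
    labels = rhythms.classify_free_running(peaks)
    expected = {"DD": "free_running", "LD": "entrained",
                "LL_low": "entrained", "LL_high": "entrained"}
    scored = {k: (v == expected[k[0]]) for k, v in labels.items()}

    power, tcv = {}, {}
    for ind, chans in res.series.items():
        power[ind] = rhythms.windowed_power(chans["activity"], cfg.start)
        tcv[ind] = daily_frame(daily_stats(chans["t_collar"]))
    rows = drivers.assemble_drivers(power, sol, tcv, nfit)
    dfit = drivers.fit_mixed_model(rows)
    return {
        "labels": {f"{k[0]}@{k[1].date()}": v for k, v in labels.items()},
        "label_accuracy": sum(scored.values()) / len(scored),
        "n_segments": len(scored),
        "betas": dfit.betas,
        "n_rows": dfit.n_rows,
    }
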