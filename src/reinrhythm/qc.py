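"""Sensor-level quality filters for the telemetry channels.

Heart rate is recorded as one 3-minute set of inter-beat intervals per
21-minute cycle, from an in-rumen acceleration sensor that is blind for
0.5 s after each detected beat — so 120 bpm is a hard ceiling.  Movement of
the animal and reticulum contractions corrupt the intervals, and the UHF
link between rumen unit and collar sometimes drops beats.  The four-step
filter below reduces the raw windows to the 'stationary' heart rate HR_s:

1. discard windows whose intervals cover < 70% of the 3 minutes;
2. discard windows recorded while the animal was active, using a cutoff at
   the density minimum between the two modes of the (always bimodal)
   activity distribution;
3. take the kernel-density mode of the per-gap instantaneous rates
   (60/interval) as the window's modal heart rate;
4. discard modal rates deviating from a long-term smooth trend by more
   than +30 or below -20 bpm.

Rumen temperature gets its own filter: a record is dropped when it differs
from the last retained record by more than 0.25 degC, which removes whole
drinking/snow-eating dip episodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .core import TelemetrySeries

log = logging.getLogger("reinrhythm")

HR_CEILING_BPM = 120.0
SENSOR_DEAD_TIME_S = 0.5  # -> ceiling = 60 / 0.5 = 120 bpm
COVERAGE_MIN = 0.70
OUTLIER_UP_BPM = 30.0  # removal strictly beyond +30 ...
OUTLIER_DOWN_BPM = -20.0  # ... or strictly below -20
TRUMEN_DELTA_MAX = 0.25  # degC between subsequent retained records
RATE_GRID = np.linspace(20.0, 120.0, 512)
ACTIVITY_GRID = np.linspace(0.0, 1.0, 512)


@dataclass
class BeatWindow:
    """One 3-minute set of inter-beat intervals and its derived modal rate."""

    start: pd.Timestamp
    intervals: np.ndarray  # seconds, each >= 0.5
    modal_hr: float | None = None  # bpm, absent until Step 3 runs
    active_flag: bool | None = None

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)

    @property
    def coverage(self) -> float:
        return float(self.intervals.sum()) / 180.0


@dataclass(frozen=True)
class ActivityClassifier:
    """Cutoff at the density minimum between the two activity modes."""

    cutoff: float
    mode_low: float
    mode_high: float


@dataclass
class QCReport:
    n_total: int = 0
    n_coverage_removed: int = 0
    n_active_removed: int = 0
    n_no_activity_record: int = 0
    n_modal_failed: int = 0
    n_outlier_removed: int = 0
    n_kept: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def gaussian_kde_density(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density with Silverman's bandwidth on a fixed grid."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    bw = 0.9 * spread * n ** (-0.2)
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (n * bw * np.sqrt(2 * np.pi))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima, boundaries included."""
    idx = []
    for i in range(len(y)):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < len(y) - 1 else -np.inf
        if y[i] > left and y[i] >= right:
            idx.append(i)
    return np.array(idx, dtype=int)


def filter_coverage(window: BeatWindow) -> bool:
    """Step 1: keep iff intervals cover at least 70% of the 3 minutes."""
    return window.coverage >= COVERAGE_MIN


def fit_activity_classifier(activity: TelemetrySeries) -> ActivityClassifier:
    """Step 2 prerequisite: cutoff from the bimodal activity distribution.

    A Gaussian kernel density is estimated over [0, 1] from the whole
    deployment; the cutoff is the density minimum between the two highest
    local maxima.  A unimodal density raises (set a manual cutoff instead).
    """
    vals = np.asarray(activity.values, dtype=float)
    dens = gaussian_kde_density(vals, ACTIVITY_GRID)
    maxima = _local_maxima(dens)
    if len(maxima) < 2:
        raise ValueError(
            "activity density is unimodal; supply a manual activity cutoff"
        )
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_i, hi_i = sorted(int(i) for i in top2)
    between = slice(lo_i, hi_i + 1)
    cut_i = lo_i + int(np.argmin(dens[between]))
    return ActivityClassifier(
        cutoff=float(ACTIVITY_GRID[cut_i]),
        mode_low=float(ACTIVITY_GRID[lo_i]),
        mode_high=float(ACTIVITY_GRID[hi_i]),
    )


def filter_active(
    window: BeatWindow, classifier: ActivityClassifier, activity_at_window: float | None
) -> bool:
    """Step 2: keep iff the concurrent activity is at or below the cutoff.

    A window with no concurrent activity record is discarded (conservative).
    """
    if activity_at_window is None:
        return False
    return float(activity_at_window) <= classifier.cutoff


def modal_heart_rate(window: BeatWindow) -> float | None:
    """Step 3: kernel-density mode of the instantaneous rates 60/interval.

    Needs at least 5 intervals; the result never exceeds the 120-bpm
    sensor ceiling.
    """
    iv = window.intervals
    if len(iv) < 5:
        log.debug("modal_heart_rate: only %d intervals; no mode", len(iv))
        return None
    rates = 60.0 / np.maximum(iv, SENSOR_DEAD_TIME_S)
    if rates.std(ddof=1) < 1e-9:
        return float(min(rates[0], HR_CEILING_BPM))
    dens = gaussian_kde_density(rates, RATE_GRID)
    return float(RATE_GRID[int(np.argmax(dens))])


def fit_hr_trend(
    t_days: np.ndarray, values: np.ndarray, knot_spacings=(10.0, 15.0, 20.0)
) -> np.ndarray:
    """Smooth long-term trend of modal heart rate over a deployment.

    Least-squares cubic regression spline with interior knots every
    ``spacing`` days; the spacing is chosen by generalized cross-validation.
    The coarsest grid caps flexibility near one effective df per 10 days.
    """
    t_days = np.asarray(t_days, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    best = None
    for sp in knot_spacings:
        interior = np.arange(t_days[0] + sp, t_days[-1] - 1e-9, sp)
        knots = np.concatenate(
            [np.repeat(t_days[0], 4), interior, np.repeat(t_days[-1] + 1e-9, 4)]
        )
        X = BSpline.design_matrix(t_days, knots, 3).toarray()
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        fitted = X @ coef
        edf = X.shape[1]
        if n <= edf:
            continue
        gcv = n * ((values - fitted) ** 2).sum() / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, fitted)
    if best is None:  # deployment too short for any knot grid
        return np.full(n, values.mean())
    return best[1]


def filter_outliers(times, values) -> np.ndarray:
    """Step 4: keep-mask for modal rates against a penalized smooth trend.

    Points with (value - trend) strictly above +30 or strictly below -20
    bpm are removed; exactly +30 / -20 is kept.  Fewer than 50 points or a
    span under 30 days passes everything through with a warning.
    """
    times = pd.DatetimeIndex(times)
    values = np.asarray(values, dtype=float)
    span_days = (times[-1] - times[0]).total_seconds() / 86400.0 if len(times) else 0.0
    if len(values) < 50 or span_days < 30.0:
        log.warning(
            "filter_outliers: %d points over %.1f days; too few for a trend, passing through",
            len(values),
            span_days,
        )
        return np.ones(len(values), dtype=bool)
    t_days = (times.asi8 - times.asi8[0]) / 86.4e12
    trend = fit_hr_trend(t_days, values)
    resid = values - trend
    return (resid <= OUTLIER_UP_BPM) & (resid >= OUTLIER_DOWN_BPM)


def filter_trumen(series: TelemetrySeries) -> TelemetrySeries:
    """Drop rumen-temperature records jumping > 0.25 degC from the last
    retained record.

    Comparing against the last *retained* value removes whole dip episodes
    (ingested cold water, snow or food) until the temperature recovers.
    """
    if series.channel != "t_rumen":
        raise ValueError("filter_trumen expects the t_rumen channel")
    v = series.values
    keep = np.ones(len(v), dtype=bool)
    if len(v) == 0:
        return series
    last = v[0]
    for i in range(1, len(v)):
        if abs(v[i] - last) > TRUMEN_DELTA_MAX:
            keep[i] = False
        else:
            last = v[i]
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_trumen(%s): removed %d records", series.individual_id, n_drop)
    return TelemetrySeries(
        "t_rumen",
        series.timestamps[keep],
        v[keep],
        individual_id=series.individual_id,
        cadence_hint=series.cadence_hint,
    )


def _activity_lookup(activity: TelemetrySeries, starts: pd.DatetimeIndex) -> np.ndarray:
    """Activity value at each beat-window start (nearest record within 90 s)."""
    at = activity.timestamps.asi8
    out = np.full(len(starts), np.nan)
    pos = np.searchsorted(at, starts.asi8)
    for k, (p, s) in enumerate(zip(pos, starts.asi8)):
        best = None
        for q in (p - 1, p):
            if 0 <= q < len(at):
                d = abs(at[q] - s)
                if best is None or d < best[0]:
                    best = (d, q)
        if best is not None and best[0] <= 90e9:
            out[k] = activity.values[best[1]]
    return out


def stationary_heart_rate(
    beats: list[BeatWindow],
    activity: TelemetrySeries,
    classifier: ActivityClassifier | None = None,
) -> tuple[TelemetrySeries, QCReport]:
    """Run the full four-step filter; returns HR_s and per-step removal counts.

    Stages only ever remove windows, never alter values, and run in the
    fixed order coverage -> activity -> modal rate -> outlier.
    """
    report = QCReport(n_total=len(beats))
    if classifier is None:
        classifier = fit_activity_classifier(activity)

    stage1 = [w for w in beats if filter_coverage(w)]
    report.n_coverage_removed = report.n_total - len(stage1)

    starts = pd.DatetimeIndex([w.start for w in stage1])
    act = _activity_lookup(activity, starts) if len(stage1) else np.array([])
    stage2 = []
    for w, a in zip(stage1, act):
        a_val = None if np.isnan(a) else float(a)
        if a_val is None:
            report.n_no_activity_record += 1
        w.active_flag = None if a_val is None else a_val > classifier.cutoff
        if filter_active(w, classifier, a_val):
            stage2.append(w)
    report.n_active_removed = len(stage1) - len(stage2)

    stage3 = []
    for w in stage2:
        w.modal_hr = modal_heart_rate(w)
        if w.modal_hr is None:
            report.n_modal_failed += 1
        else:
            stage3.append(w)

    times = pd.DatetimeIndex([w.start for w in stage3])
    vals = np.array([w.modal_hr for w in stage3])
    keep = filter_outliers(times, vals) if len(stage3) else np.array([], dtype=bool)
    report.n_outlier_removed = int((~keep).sum())
    report.n_kept = int(keep.sum())

    hr = TelemetrySeries(
        "hr_stationary",
        times[keep],
        vals[keep],
        individual_id=activity.individual_id,
    )
    return hr, report
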