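"""Lomb-Scargle rhythm detection.

The classical Lomb-Scargle periodogram (with the per-frequency time offset)
is the natural spectral tool for these data: sampling is irregular once the
QC filters have removed records, and the method restricts all computation to
actually measured values.  The raw power at a period — the goodness of fit
of the best sinusoid — is divided by twice the series variance, so that
under a white-noise null each normalized power z follows an exponential
distribution, and the minimum p over a scanned band can be tested with

    p = 1 - (1 - exp(-z)) ** M

where M is the number of periods scanned.  The scanned grid is even in
frequency with an oversampling factor (default 2) relative to the natural
1/T spacing of the window length T; at that density M tracks the effective
number of independent trials closely, which keeps the band-minimum p test
calibrated (see docs/methods.md for the measured type-I error).

Two bands matter: 0.5-30 h (ultradian through circadian) and 21-27 h
(diel/circadian focus), scanned over consecutive 15-day windows or over
whole photic seasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .core import TelemetrySeries, Window, slice_windows
from .solar import SeasonWindows

log = logging.getLogger("reinrhythm")

DIEL_BAND_H = (21.0, 27.0)
FULL_BAND_H = (0.5, 30.0)
DEFAULT_OVERSAMPLE = 2.0
ENTRAINMENT_TOL_H = 0.25


@dataclass
class Periodogram:
    periods: np.ndarray  # hours, strictly monotone
    powers: np.ndarray  # normalized Lomb-Scargle power, >= 0
    n_obs: int
    M: int  # number of periods scanned


@dataclass(frozen=True)
class RhythmPeak:
    tau: float  # hours
    power: float  # normalized power z
    p_value: float


def detrend(series: TelemetrySeries) -> TelemetrySeries:
    """Subtract the ordinary least-squares line on (time, value)."""
    if len(series) < 3:
        raise ValueError("detrend needs at least 3 points")
    t = series.hours_since()
    X = np.column_stack([np.ones(len(t)), t])
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    return TelemetrySeries(
        series.channel,
        series.timestamps,
        series.values - X @ beta,
        individual_id=series.individual_id,
        cadence_hint=series.cadence_hint,
    )


def period_grid(band_h, duration_h: float, oversample: float = DEFAULT_OVERSAMPLE):
    """Period grid (hours) even in frequency across the band.

    The number of periods is ``ceil(oversample * T * (f_max - f_min)) + 1``
    — the natural Fourier count for the window length T times the
    oversampling factor.
    """
    lo, hi = sorted(band_h)
    if lo <= 0:
        raise ValueError("band must be positive")
    fmin, fmax = 1.0 / hi, 1.0 / lo
    M = int(np.ceil(oversample * duration_h * (fmax - fmin))) + 1
    freqs = np.linspace(fmin, fmax, max(M, 2))
    return 1.0 / freqs  # descending periods


def lomb_scargle(
    series: TelemetrySeries,
    band: tuple = DIEL_BAND_H,
    M: int | None = None,
    oversample: float = DEFAULT_OVERSAMPLE,
) -> Periodogram:
    """Normalized Lomb-Scargle periodogram of a (detrended) series.

    Classical periodogram with per-frequency time offset, divided by twice
    the series variance so the null distribution of each power is Exp(1).
    ``M`` overrides the grid size; otherwise it follows ``oversample``.
    """
    if len(series) < 10:
        raise ValueError("lomb_scargle needs at least 10 points")
    t = series.hours_since()
    y = series.values - series.values.mean()
    var = y.var()
    if var <= 0:
        raise ValueError("zero-variance series: normalized power undefined")
    duration = t[-1] - t[0]
    if M is not None:
        lo, hi = sorted(band)
        periods = 1.0 / np.linspace(1.0 / hi, 1.0 / lo, M)
    else:
        periods = period_grid(band, duration, oversample)
    omega = 2.0 * np.pi / periods
    raw = lombscargle(t, y, omega)  # = explained SS of best sinusoid / 2
    powers = raw / var  # = explained SS / (2 * variance)
    return Periodogram(
        periods=periods, powers=powers, n_obs=len(y), M=len(periods)
    )


def significance(power: float, M: int) -> float:
    """p-value of one normalized power against the exponential null,
    corrected for the M periods scanned: p = 1 - (1 - e^-z)^M."""
    if np.any(np.asarray(power) < 0) or M < 1:
        raise ValueError("power must be >= 0 and M >= 1")
    z = np.asarray(power, dtype=float)
    with np.errstate(divide="ignore"):
        p = -np.expm1(M * np.log1p(-np.exp(-z)))  # stable 1 - (1 - e^-z)^M
    p = np.where(z <= 0, 1.0, p)
    return float(np.squeeze(p)) if np.ndim(power) == 0 else p


def extract_peaks(pg: Periodogram, alpha: float = 0.05) -> list[RhythmPeak]:
    """All significant local maxima of the periodogram, power-descending.

    Boundary grid points count as candidate maxima, so a monotone
    periodogram yields at most one (boundary) peak.
    """
    y = pg.powers
    peaks = []
    for i in range(len(y)):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < len(y) - 1 else -np.inf
        if y[i] > left and y[i] >= right:
            p = significance(float(y[i]), pg.M)
            if p < alpha:
                peaks.append(RhythmPeak(tau=float(pg.periods[i]), power=float(y[i]), p_value=p))
    peaks.sort(key=lambda pk: pk.power, reverse=True)
    return peaks


def windowed_power(
    series: TelemetrySeries,
    anchor,
    width_days: float = 15.0,
    band: tuple = DIEL_BAND_H,
    alpha: float = 0.05,
    oversample: float = DEFAULT_OVERSAMPLE,
    min_points: int = 10,
) -> list[tuple[Window, float | None]]:
    """Mean normalized power of significant band peaks per 15-day window.

    Windows with no significant peak (or too few records) contribute an
    absent value, not zero — the seasonal averages are means over
    significant rhythms only.  The window width must cover at least ten
    cycles of the longest band period.
    """
    if width_days * 24.0 < 10.0 * max(band):
        raise ValueError("window too short: need at least ten cycles of the longest period")
    out = []
    for win, sub in slice_windows(series, anchor, width_days):
        if len(sub) < max(min_points, 10):
            log.debug("windowed_power: window %s has %d points; absent", win.label, len(sub))
            out.append((win, None))
            continue
        try:
            pg = lomb_scargle(detrend(sub), band=band, oversample=oversample)
        except ValueError:
            out.append((win, None))
            continue
        peaks = extract_peaks(pg, alpha=alpha)
        if not peaks:
            out.append((win, None))
        else:
            out.append((win, float(np.mean([p.power for p in peaks]))))
    return out


def season_peaks(
    series: TelemetrySeries,
    seasons: SeasonWindows,
    band: tuple = DIEL_BAND_H,
    alpha: float = 0.05,
    oversample: float = DEFAULT_OVERSAMPLE,
    min_points: int = 50,
) -> dict:
    """Significant band peaks per photic-season segment.

    Keys are ``(label, start_date)`` so repeated labels (two LD spans per
    year) stay separate; values are power-sorted peak lists.  Segments
    shorter than ten cycles of the longest band period are skipped.
    """
    out = {}
    for label, start, end in seasons.segments:
        if (pd.Timestamp(end) - pd.Timestamp(start)) / pd.Timedelta(hours=1) < 10.0 * max(band):
            log.info("season_peaks: segment %s from %s too short for the band; skipped", label, start)
            continue
        win = Window(pd.Timestamp(start), pd.Timestamp(end), label=label)
        m = win.contains(series.timestamps)
        sub = TelemetrySeries(
            series.channel,
            series.timestamps[m],
            series.values[m],
            individual_id=series.individual_id,
        )
        if len(sub) < min_points:
            out[(label, pd.Timestamp(start))] = []
            continue
        pg = lomb_scargle(detrend(sub), band=band, oversample=oversample)
        out[(label, pd.Timestamp(start))] = extract_peaks(pg, alpha=alpha)
    return out


def classify_free_running(
    peaks_by_season: dict, tol_h: float = ENTRAINMENT_TOL_H
) -> dict:
    """Label each season segment entrained / free_running / arrhythmic.

    Entrained when the strongest significant 21-27 h peak lies within
    24 +/- tol hours; free-running when significant peaks exist but the
    strongest sits outside the tolerance; arrhythmic when none is
    significant.
    """
    labels = {}
    for key, peaks in peaks_by_season.items():
        if not peaks:
            labels[key] = "arrhythmic"
        elif abs(peaks[0].tau - 24.0) <= tol_h:
            labels[key] = "entrained"
        else:
            labels[key] = "free_running"
    return labels


def actogram_matrix(series: TelemetrySeries, bin_minutes: int = 30) -> pd.DataFrame:
    """Days x time-of-day matrix of mean values, for actogram-style plots."""
    df = pd.DataFrame({"value": series.values}, index=series.timestamps)
    day = df.index.floor("D")
    tod = (df.index - day).total_seconds() // (bin_minutes * 60)
    return df.groupby([day, tod])["value"].mean().unstack()
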