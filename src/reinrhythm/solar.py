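"""Clear-sky solar geometry at the study site.

Geometric solar elevation (no atmospheric refraction) from the Spencer
Fourier series for declination and the equation of time, direct maximum
radiation through a clear atmosphere from the air-mass formula, and the
photic-season segmentation used throughout: a day belongs to continual
light (LL) when the sun's geometric centre never drops more than 6 deg
below the horizon (civil twilight bound), to continual darkness (DD) when
it never rises above -6 deg, and to day/night alternation (LD) otherwise.

Default site: 78.0 N, 16.0 E (centre of the Nordenskioldland study area,
77 50'-78 20' N, 15 00'-17 30' E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("reinrhythm")

SITE_LAT = 78.0
SITE_LON = 16.0
#: northern boundary of the study area, used for the printed-date checks
SITE_LAT_NORTH = 78.33

CIVIL_TWILIGHT_DEG = -6.0
SOLAR_CONSTANT_KW = 1.353  # kW/m^2


@dataclass(frozen=True)
class SolarDayProfile:
    date: pd.Timestamp
    latitude: float
    longitude: float
    min_elevation: float
    max_elevation: float
    radiation_variance: float  # (kW/m^2)^2 over the day's time grid
    twilight_crossings: tuple  # UTC instants where elevation crosses -6 deg


def _fractional_year(idx: pd.DatetimeIndex) -> np.ndarray:
    """Orbital phase (radians) for the Spencer series.

    Calendar day-of-year phase, the convention of the standard zenith-angle
    routines used in biologging work.  Its declination can deviate from a
    modern ephemeris by up to ~0.5 deg near the equinoxes, which is exactly
    the convention that fixes the continual-daylight calendar dates at the
    study site; see docs/methods.md.
    """
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = (
        idx.hour.to_numpy()
        + idx.minute.to_numpy() / 60.0
        + idx.second.to_numpy() / 3600.0
    ).astype(float)
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)


def solar_declination(gamma: np.ndarray) -> np.ndarray:
    """Declination in degrees from the Spencer Fourier series."""
    return np.degrees(
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def equation_of_time(gamma: np.ndarray) -> np.ndarray:
    """Equation of time in minutes (Spencer series)."""
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def solar_elevation(instants, latitude: float, longitude: float) -> np.ndarray:
    """Geometric elevation (deg) of the Sun's centre at UTC ``instants``.

    No refraction correction; vectorised over instants.
    """
    if abs(latitude) > 90:
        raise ValueError("latitude must be within [-90, 90]")
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(instants, dtype="datetime64[ns]")))
    hour = (
        idx.hour.to_numpy()
        + idx.minute.to_numpy() / 60.0
        + idx.second.to_numpy() / 3600.0
    ).astype(float)
    gamma = _fractional_year(idx)
    dec = np.radians(solar_declination(gamma))
    # true solar time in hours: UTC + longitude offset + equation of time
    tst = hour + longitude / 15.0 + equation_of_time(gamma) / 60.0
    ha = np.radians(15.0 * (tst - 12.0))
    lat = np.radians(latitude)
    sin_el = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def air_mass(zenith_deg) -> np.ndarray:
    """Kasten-Young relative air mass; finite down to the horizon."""
    z = np.asarray(zenith_deg, dtype=float)
    return 1.0 / (np.cos(np.radians(z)) + 0.50572 * (96.07995 - z) ** -1.6364)


def direct_max_radiation(elevation_deg) -> np.ndarray:
    """Direct beam irradiance (kW/m^2) through a clear atmosphere.

    0 when the sun is at or below the horizon, else
    1.353 * 0.7 ** (AM ** 0.678) with Kasten-Young air mass.
    """
    el = np.asarray(elevation_deg, dtype=float)
    out = np.zeros_like(el)
    up = el > 0
    if np.any(up):
        am = air_mass(90.0 - el[up])
        out[up] = SOLAR_CONSTANT_KW * 0.7 ** (am ** 0.678)
    return out if out.ndim else float(out)


def day_profile(
    date, latitude: float = SITE_LAT, longitude: float = SITE_LON, grid_step: int = 180
) -> SolarDayProfile:
    """Elevation extrema, radiation variance and twilight crossings for one day.

    ``grid_step`` (seconds) must divide 86400; the default 180 s matches the
    telemetry cadence.  The radiation variance is the population variance of
    direct maximum radiation over the day's grid.
    """
    if 86400 % grid_step:
        raise ValueError("grid_step must divide 86400")
    day = pd.Timestamp(date).floor("D")
    grid = day + pd.to_timedelta(np.arange(0, 86400, grid_step), unit="s")
    el = solar_elevation(grid, latitude, longitude)
    rad = direct_max_radiation(el)
    above = el >= CIVIL_TWILIGHT_DEG
    crossings = []
    flips = np.nonzero(np.diff(above.astype(int)))[0]
    for i in flips:
        # linear interpolation of the -6 deg crossing instant
        f = (CIVIL_TWILIGHT_DEG - el[i]) / (el[i + 1] - el[i])
        crossings.append(grid[i] + f * (grid[i + 1] - grid[i]))
    return SolarDayProfile(
        date=day,
        latitude=latitude,
        longitude=longitude,
        min_elevation=float(el.min()),
        max_elevation=float(el.max()),
        radiation_variance=float(np.asarray(rad).var()),
        twilight_crossings=tuple(crossings),
    )


def light_label(profile: SolarDayProfile) -> str:
    """DD / LD / LL classification of one day from its elevation extrema."""
    if profile.max_elevation < CIVIL_TWILIGHT_DEG:
        return "DD"
    if profile.min_elevation >= CIVIL_TWILIGHT_DEG:
        return "LL"
    return "LD"


def day_table(
    start, end, latitude: float = SITE_LAT, longitude: float = SITE_LON, grid_step: int = 180
) -> pd.DataFrame:
    """Per-day solar summary over [start, end): one row per calendar day.

    Columns: date, min_elevation, max_elevation, radiation_variance,
    light_label.
    """
    days = pd.date_range(pd.Timestamp(start).floor("D"), pd.Timestamp(end), freq="D", inclusive="left")
    rows = []
    for d in days:
        p = day_profile(d, latitude, longitude, grid_step)
        rows.append(
            (d, p.min_elevation, p.max_elevation, p.radiation_variance, light_label(p))
        )
    return pd.DataFrame(
        rows,
        columns=["date", "min_elevation", "max_elevation", "radiation_variance", "light_label"],
    )


def find_light_season_bounds(
    year: int, latitude: float = SITE_LAT_NORTH, longitude: float = SITE_LON, grid_step: int = 600
):
    """First/last continual-light and continual-darkness days of a calendar year.

    LL days have minimum elevation >= -6 deg; DD days have maximum elevation
    < -6 deg.  Returns ``(first_LL, last_LL, first_DD, last_DD)`` as
    Timestamps; a bound is None when the latitude produces no such day.
    """
    tab = day_table(f"{year}-01-01", f"{year + 1}-01-01", latitude, longitude, grid_step)
    ll = tab.loc[tab["light_label"] == "LL", "date"]
    dd = tab.loc[tab["light_label"] == "DD", "date"]
    first_ll = ll.iloc[0] if len(ll) else None
    last_ll = ll.iloc[-1] if len(ll) else None
    first_dd = dd.iloc[0] if len(dd) else None
    last_dd = dd.iloc[-1] if len(dd) else None
    return first_ll, last_ll, first_dd, last_dd


@dataclass
class SeasonWindows:
    """Contiguous dated photic/vegetation season segments.

    Labels follow the annual sequence DD -> LD -> LL_low -> LL_high -> LD
    (-> DD), with the continual-light span split at the first date the
    fitted NDVI curve exceeds 0.
    """

    segments: list  # of (label, start Timestamp, end Timestamp); end exclusive

    def label_for(self, instant) -> str | None:
        t = pd.Timestamp(instant)
        for label, start, end in self.segments:
            if start <= t < end:
                return label
        return None

    def spans(self, label: str) -> list:
        return [(s, e) for lab, s, e in self.segments if lab == label]


def segment_seasons(
    study_start,
    study_end,
    ndvi_curve=None,
    latitude: float = SITE_LAT,
    longitude: float = SITE_LON,
    grid_step: int = 600,
    ndvi_crossing=None,
) -> SeasonWindows:
    """Segment [study_start, study_end) into DD/LD/LL_low/LL_high seasons.

    Day labels come from solar geometry; the LL span is split at the first
    date the fitted NDVI curve (``ndvi_curve``: callable day-of-year ->
    NDVI, or an explicit ``ndvi_crossing`` date) exceeds 0.  If the NDVI
    curve never goes positive, the whole LL span is labelled LL_low and a
    warning is logged.
    """
    tab = day_table(study_start, study_end, latitude, longitude, grid_step)
    labels = tab["light_label"].to_numpy()
    dates = tab["date"]

    # split each LL run at the NDVI zero-crossing
    out_labels = []
    for i, lab in enumerate(labels):
        if lab != "LL":
            out_labels.append(lab)
            continue
        d = dates.iloc[i]
        if ndvi_crossing is not None:
            pos = d >= pd.Timestamp(ndvi_crossing)
        elif ndvi_curve is not None:
            pos = float(ndvi_curve(float(d.dayofyear))) > 0.0
        else:
            pos = False
        out_labels.append("LL_high" if pos else "LL_low")
    if "LL" in labels and "LL_high" not in out_labels and (
        ndvi_curve is not None or ndvi_crossing is not None
    ):
        log.warning("segment_seasons: fitted NDVI never positive; whole LL span is LL_low")

    segments = []
    run_start = 0
    for i in range(1, len(out_labels) + 1):
        if i == len(out_labels) or out_labels[i] != out_labels[run_start]:
            seg_end = (
                dates.iloc[i] if i < len(out_labels) else pd.Timestamp(study_end)
            )
            segments.append((out_labels[run_start], dates.iloc[run_start], seg_end))
            run_start = i
    return SeasonWindows(segments=segments)
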