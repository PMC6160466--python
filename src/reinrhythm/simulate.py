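"""Seeded generator of multi-individual, multi-channel telemetry.

The generator emulates the statistical structure of a High-Arctic reindeer
biologging deployment so that every pipeline stage can be exercised against
known ground truth:

* each channel carries a circannual raised-cosine peak on a stable baseline
  (same functional form the seasonal model fits, so recovery is a closed
  loop);
* a diel component whose period is scheduled by photic season — 24 h while
  entrained (LD and continual light) and a free-running 23.4 h by default
  through the Polar Night — with phase kept continuous across season
  boundaries;
* seasonal attenuation of diel amplitude (x0.4 in DD and in the vegetated
  part of the Midnight Sun by default) plus a log-linear coupling of the
  amplitude to the daily variance of solar radiation and to NDVI, giving
  the mixed-model stage a recoverable truth;
* ultradian foraging/rumination components (~6 h in winter, ~4 h during
  peak vegetation);
* sensor artifacts at configured rates: drinking dips in rumen temperature,
  motion-corrupted inter-beat intervals, UHF coverage failures, +50 bpm
  contamination spikes, and random record dropout — each one labelled.

Activity is emitted with a bimodal marginal (the rhythm modulates the
probability of being in the active state); heart rate is emitted as raw
3-minute sets of inter-beat intervals >= 0.5 s per 21-minute cycle, so the
120-bpm ceiling arises mechanistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import TelemetrySeries
from .qc import BeatWindow, SENSOR_DEAD_TIME_S
from .seasonal import ANNUAL_PERIOD_D, BaselineCosineFit, baseline_cosine_predict, first_positive_crossing
from .solar import SITE_LAT, SITE_LON, day_table, segment_seasons, SeasonWindows

log = logging.getLogger("reinrhythm")

# marginal means of the two activity modes (Beta-distributed switch output)
_ACT_HI = 1.0 - 1.0 / 31.0  # active mode, ~0.968
_ACT_LO = 1.0 / 43.0  # inactive mode, ~0.023


def _rise_to_w(rise_days: float) -> float:
    """Fractional peak width from onset-to-acrophase rise time."""
    return 2.0 * rise_days / ANNUAL_PERIOD_D


@dataclass
class SimConfig:
    """Study conditions for the synthetic deployment.

    Defaults follow the field system: a Nov 15 - Nov 15 study year at the
    site latitude, three individuals, annual profiles with the reported
    percentage increases and rise times, entrained 24-h rhythms outside
    the Polar Night and a free-running 23.4-h rhythm within it.
    """

    seed: int = 0
    individuals: int = 3
    start: str = "2012-11-15"
    end: str = "2013-11-15"
    latitude: float = SITE_LAT
    longitude: float = SITE_LON
    # per-channel annual raised-cosine profiles (b, H, t_peak doy, w)
    annual: dict = field(default_factory=lambda: {
        "hr": (40.0, 50.4, 197.0, _rise_to_w(65.0)),  # +126% in 65 d
        "t_rumen": (38.3, 0.766, 210.0, _rise_to_w(77.0)),  # +2% in 77 d
        "activity": (0.25, 0.0975, 221.0, _rise_to_w(140.0)),  # +39% in 140 d
        "head_moves": (20.0, 20.2, 198.0, _rise_to_w(65.0)),  # +101% in 65 d
        "t_collar": (-15.0, 20.0, 203.5, 0.60),  # winter ~-15, summer ~+5 degC
        "ndvi": (-0.1, 0.7, 205.0, 0.36),  # crosses 0 in early June
    })
    # diel rhythm: per-season period (h) and amplitude multiplier
    tau_by_season: dict = field(default_factory=lambda: {
        "DD": 23.4, "LD": 24.0, "LL_low": 24.0, "LL_high": 24.0,
    })
    amp_mult_by_season: dict = field(default_factory=lambda: {
        "DD": 0.4, "LD": 1.0, "LL_low": 1.0, "LL_high": 0.4,
    })
    # diel amplitudes in channel units (activity: on the P(active) scale)
    diel_amp: dict = field(default_factory=lambda: {
        "hr": 5.0, "t_rumen": 0.25, "activity": 0.14,
        "head_moves": 0.30, "t_collar": 1.5,
    })
    # ultradian components: ~6 h in winter, ~4 h during peak vegetation
    ultradian_period_winter_h: float = 6.0
    ultradian_period_summer_h: float = 4.0
    ultradian_amp: dict = field(default_factory=lambda: {
        "activity": 0.08, "head_moves": 0.15, "t_rumen": 0.04, "hr": 0.5,
    })
    # log-linear coupling of diel amplitude to z-scored daily zeitgebers
    coupling_beta_sun: float = 0.25
    coupling_beta_ndvi: float = -0.25
    # noise
    noise_sd: dict = field(default_factory=lambda: {
        "activity": 0.05, "t_collar": 0.8, "t_rumen": 0.05,
        "hr": 1.0, "ndvi": 0.02,
    })
    beat_jitter_s: float = 0.03
    # artifact rates
    drink_events_per_day: float = 4.0
    drink_depth_range: tuple = (1.5, 2.5)  # degC
    motion_window_frac: float = 0.15
    motion_interval_frac: float = 0.20
    lowcov_window_frac: float = 0.08
    spike_frac: float = 0.05
    spike_bpm: float = 50.0
    record_dropout_frac: float = 0.10
    hr_ceiling: float = 120.0

    def validate(self):
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("end must be after start")
        if not 0 <= self.record_dropout_frac < 1:
            raise ValueError("dropout fraction must be in [0, 1)")
        for s, tau in self.tau_by_season.items():
            if not 20.0 < tau < 28.0:
                raise ValueError(f"tau for {s} outside (20, 28) h")
        for a in self.amp_mult_by_season.values():
            if a < 0:
                raise ValueError("amplitude multipliers must be >= 0")


def default_paper_config(seed: int = 0) -> SimConfig:
    """The default study conditions (see class docstring)."""
    return SimConfig(seed=seed)


@dataclass
class GroundTruth:
    """Labels for every injected feature of one simulated deployment."""

    annual: dict  # channel -> (b, H, t_peak, w)
    tau_by_season: dict
    amp_mult_by_season: dict
    coupling_betas: dict  # {"sun": ..., "ndvi": ...}
    ndvi_crossing: pd.Timestamp
    seasons: SeasonWindows
    per_individual: dict = field(default_factory=dict)
    # per individual: dict with keys
    #   spike_starts, motion_starts, lowcov_starts : DatetimeIndex of beat windows
    #   drink_records : DatetimeIndex of labelled t_rumen dip records
    #   dropout : {channel: DatetimeIndex of dropped 3-min records}
    #   true_hr : DataFrame(start, true_bpm) for every emitted beat window


@dataclass
class SimResult:
    series: dict  # individual -> channel -> TelemetrySeries
    beats: dict  # individual -> list[BeatWindow]
    truth: GroundTruth
    config: SimConfig


def ndvi_truth_fit(config: SimConfig) -> BaselineCosineFit:
    """The configured NDVI curve as a (noiseless) fit object."""
    b, H, tp, w = config.annual["ndvi"]
    return BaselineCosineFit(
        b=b, H=H, t_peak=tp, w=w, residual_sd=0.0, baseline_included=True
    )


def generate_ndvi(config: SimConfig, year: int | None = None) -> tuple[TelemetrySeries, pd.Timestamp]:
    """16-day NDVI composites for one calendar year plus the true crossing date.

    Composite timestamps are the midpoints of the standard 16-day periods
    from Jan 1 (23 composites per year).
    """
    config.validate()
    if year is None:
        mid = pd.Timestamp(config.start) + (pd.Timestamp(config.end) - pd.Timestamp(config.start)) / 2
        year = mid.year
    rng = np.random.default_rng([config.seed, 7919])
    starts = pd.Timestamp(year=year, month=1, day=1) + pd.to_timedelta(
        16 * np.arange(23), unit="D"
    )
    mid_ts = starts + pd.Timedelta(days=8)
    doy = mid_ts.dayofyear.to_numpy(dtype=float)
    b, H, tp, w = config.annual["ndvi"]
    vals = baseline_cosine_predict(doy, b, H, tp, w) + rng.normal(
        0.0, config.noise_sd["ndvi"], len(doy)
    )
    series = TelemetrySeries("ndvi", mid_ts, vals, individual_id="site")
    crossing = first_positive_crossing(ndvi_truth_fit(config), year)
    return series, crossing


def _season_arrays(config: SimConfig, days: pd.DatetimeIndex):
    """Per-day season label, z-scored radiation variance and z-scored NDVI."""
    tab = day_table(days[0], days[-1] + pd.Timedelta(days=1),
                    config.latitude, config.longitude, grid_step=600)
    crossing = first_positive_crossing(ndvi_truth_fit(config), (days[0] + (days[-1] - days[0]) / 2).year)
    seasons = segment_seasons(
        days[0], days[-1] + pd.Timedelta(days=1),
        latitude=config.latitude, longitude=config.longitude,
        grid_step=600, ndvi_crossing=crossing,
    )
    labels = np.array([seasons.label_for(d) for d in days])
    sun_var = tab.set_index("date")["radiation_variance"].reindex(days).to_numpy()
    ndvi = ndvi_truth_fit(config).predict(days.dayofyear.to_numpy(dtype=float))

    def z(x):
        sd = x.std()
        if not np.isfinite(sd) or sd < 1e-12:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return seasons, labels, z(sun_var), z(np.asarray(ndvi)), crossing


def _cum_phase(dt_h: float, periods_h: np.ndarray) -> np.ndarray:
    """Phase (radians) continuous in time for a piecewise-constant period."""
    return np.cumsum(2.0 * np.pi * dt_h / periods_h)


def generate(config: SimConfig | None = None, channels=None) -> SimResult:
    """Simulate the full deployment; byte-reproducible for a given seed.

    ``channels`` restricts the emitted 3-minute channels (heart-rate beat
    windows are always emitted); default is all of activity, head_moves,
    t_collar, t_rumen.
    """
    config = config or default_paper_config()
    config.validate()
    if channels is None:
        channels = ("activity", "head_moves", "t_collar", "t_rumen")

    start, end = pd.Timestamp(config.start), pd.Timestamp(config.end)
    ts3 = pd.date_range(start, end, freq="180s", inclusive="left")
    n3 = len(ts3)
    days = pd.date_range(start.floor("D"), end, freq="D", inclusive="left")
    seasons, day_labels, z_sun, z_ndvi, crossing = _season_arrays(config, days)

    day_idx = ((ts3.asi8 - days[0].value) // 86_400_000_000_000).astype(int)
    rec_season = day_labels[day_idx]
    dt_h = 0.05  # 3 minutes

    tau = np.array([config.tau_by_season[s] for s in rec_season])
    phase = _cum_phase(dt_h, tau)
    uper = np.where(
        rec_season == "LL_high",
        config.ultradian_period_summer_h,
        config.ultradian_period_winter_h,
    )
    uphase = _cum_phase(dt_h, uper)
    season_mult = np.array([config.amp_mult_by_season[s] for s in rec_season])
    coupling = np.exp(
        config.coupling_beta_sun * z_sun[day_idx]
        + config.coupling_beta_ndvi * z_ndvi[day_idx]
    )
    mult = season_mult * coupling
    diel = mult * np.cos(phase)
    ultra = np.cos(uphase)
    doy3 = ts3.dayofyear.to_numpy(dtype=float)

    def annual(channel):
        b, H, tp, w = config.annual[channel]
        return baseline_cosine_predict(doy3, b, H, tp, w)

    series: dict = {}
    beats: dict = {}
    per_ind: dict = {}

    for k in range(config.individuals):
        ind = f"sim{k + 1}"
        rng = np.random.default_rng([config.seed, k])
        out: dict = {}
        labels: dict = {"dropout": {}}

        # ---- activity: rhythm modulates P(active); marginal is bimodal ----
        p_act = (annual("activity") - _ACT_LO) / (_ACT_HI - _ACT_LO)
        p_act = p_act + config.diel_amp["activity"] * diel \
            + config.ultradian_amp["activity"] * ultra \
            + rng.normal(0.0, config.noise_sd["activity"], n3)
        p_act = np.clip(p_act, 0.01, 0.99)
        active = rng.random(n3) < p_act
        act_vals = np.where(
            active, 1.0 - rng.beta(1.0, 30.0, n3), rng.beta(1.0, 42.0, n3)
        )

        # ---- head movements: Poisson counts, multiplicative modulation ----
        lam = annual("head_moves") * np.clip(
            1.0 + config.diel_amp["head_moves"] * diel
            + config.ultradian_amp["head_moves"] * ultra,
            0.0, None,
        )
        hm_vals = rng.poisson(lam).astype(float)

        # ---- collar temperature: diel modulation only outside DD, with a
        # day-level weather factor so its daily variance is not a proxy for
        # the radiation/NDVI coupling driving the behavioural rhythms ----
        weather = rng.uniform(0.4, 1.6, len(days))[day_idx]
        tc_diel = np.where(
            rec_season == "DD", 0.0,
            config.diel_amp["t_collar"] * weather * np.cos(phase),
        )
        tc_vals = annual("t_collar") + tc_diel + rng.normal(0.0, config.noise_sd["t_collar"], n3)

        # ---- rumen temperature with labelled drinking dips ----
        tr_clean = annual("t_rumen") + config.diel_amp["t_rumen"] * diel \
            + config.ultradian_amp["t_rumen"] * ultra
        tr_vals = tr_clean + rng.normal(0.0, config.noise_sd["t_rumen"], n3)
        dip_dev = np.zeros(n3)
        n_events = rng.poisson(config.drink_events_per_day * len(days))
        ev_starts = rng.integers(0, n3 - 40, size=n_events)
        core = np.array([-0.5, -0.9, -1.0, -1.0, -0.9])
        rec_tail = -0.9 * np.exp(-np.arange(1, 13) / 4.0)
        shape = np.concatenate([core, rec_tail])
        for s0 in ev_starts:
            depth = rng.uniform(*config.drink_depth_range)
            seg = slice(s0, s0 + len(shape))
            dip_dev[seg] = np.minimum(dip_dev[seg], depth * shape[: n3 - s0])
        tr_vals = tr_vals + dip_dev
        drink_mask = dip_dev < -0.25

        # ---- per-channel record dropout ----
        chan_arrays = {
            "activity": act_vals, "head_moves": hm_vals,
            "t_collar": tc_vals, "t_rumen": tr_vals,
        }
        for ch in channels:
            keep = rng.random(n3) >= config.record_dropout_frac
            labels["dropout"][ch] = ts3[~keep]
            out[ch] = TelemetrySeries(ch, ts3[keep], chan_arrays[ch][keep], individual_id=ind)
        labels["drink_records"] = ts3[drink_mask & (~pd.Index(ts3).isin(labels["dropout"].get("t_rumen", [])))] \
            if "t_rumen" in channels else ts3[drink_mask]

        # ---- heart rate: raw inter-beat intervals every 21 minutes ----
        bw_starts = pd.date_range(start, end, freq="1260s", inclusive="left")
        nb = len(bw_starts)
        bw_idx = ((bw_starts.asi8 - ts3.asi8[0]) // 180_000_000_000).astype(int)
        hr_det = annual("hr") + config.diel_amp["hr"] * diel \
            + config.ultradian_amp["hr"] * ultra
        true_bpm = hr_det[bw_idx]
        bw_active = active[bw_idx]

        lowcov = rng.random(nb) < config.lowcov_window_frac
        motion = (~lowcov) & (rng.random(nb) < config.motion_window_frac)
        eligible = (~bw_active) & (~lowcov) & (~motion)
        spike = eligible & (rng.random(nb) < config.spike_frac)

        h_real = true_bpm + rng.normal(0.0, config.noise_sd["hr"], nb)
        h_real = h_real + np.where(bw_active, rng.uniform(15.0, 35.0, nb), 0.0)
        h_real = h_real + np.where(spike, config.spike_bpm, 0.0)
        h_real = np.clip(h_real, 20.0, 240.0)

        cov_target = np.where(lowcov, rng.uniform(0.25, 0.65, nb), rng.uniform(0.92, 1.0, nb))
        bws = []
        for i in range(nb):
            mean_iv = 60.0 / h_real[i]
            n_iv = max(int(180.0 * cov_target[i] / mean_iv), 0)
            iv = rng.normal(mean_iv, config.beat_jitter_s, n_iv)
            iv = np.maximum(iv, SENSOR_DEAD_TIME_S)
            if motion[i] and n_iv:
                m = rng.random(n_iv) < config.motion_interval_frac
                iv[m] = rng.uniform(2.0, 4.0, int(m.sum()))
            bws.append(BeatWindow(start=bw_starts[i], intervals=iv))
        beats[ind] = bws

        labels["spike_starts"] = bw_starts[spike]
        labels["motion_starts"] = bw_starts[motion]
        labels["lowcov_starts"] = bw_starts[lowcov]
        labels["true_hr"] = pd.DataFrame({"start": bw_starts, "true_bpm": true_bpm})
        series[ind] = out
        per_ind[ind] = labels

    truth = GroundTruth(
        annual=dict(config.annual),
        tau_by_season=dict(config.tau_by_season),
        amp_mult_by_season=dict(config.amp_mult_by_season),
        coupling_betas={"sun": config.coupling_beta_sun, "ndvi": config.coupling_beta_ndvi},
        ndvi_crossing=crossing,
        seasons=seasons,
        per_individual=per_ind,
    )
    return SimResult(series=series, beats=beats, truth=truth, config=config)
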