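"""Core time-series containers and plumbing.

A :class:`TelemetrySeries` is one channel of timestamped measurements for one
animal at a nominal cadence with gaps: activity proportion, head-movement
counts, collar or rumen temperature (3-minute cadence), stationary heart rate
(21-minute cadence), or 16-day NDVI composites.  All timestamps are UTC and
tz-naive; local solar time is only ever derived downstream from longitude.

Records are never imputed — every downstream statistic operates on present
values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("reinrhythm")

#: nominal seconds between records, per channel
CADENCE_S = {
    "activity": 180,
    "head_moves": 180,
    "t_collar": 180,
    "t_rumen": 180,
    "hr_stationary": 1260,
    "ndvi": 16 * 86400,
}

#: per-channel validity checks applied row-wise on read (inclusive bounds);
#: None disables the bound.  head_moves must additionally be integral.
RANGE_CHECKS = {
    "activity": (0.0, 1.0),
    "head_moves": (0.0, None),
    "hr_stationary": (0.0, 120.0),
    "ndvi": (-1.0, 1.0),
    "t_collar": (None, None),
    "t_rumen": (None, None),
}


@dataclass
class TelemetrySeries:
    """One channel of timestamped measurements for one individual."""

    channel: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    individual_id: str = ""
    cadence_hint: float | None = None

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps.asi8)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0)) + 1
                raise ValueError(
                    f"timestamps not strictly increasing at row {i} "
                    f"({self.timestamps[i]})"
                )
        if self.cadence_hint is None:
            self.cadence_hint = CADENCE_S.get(self.channel)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "individual_id": self.individual_id,
                "value": self.values,
            }
        )

    def hours_since(self, origin: pd.Timestamp | None = None) -> np.ndarray:
        """Observation times in hours since ``origin`` (default: first record)."""
        if origin is None:
            origin = self.timestamps[0]
        return (self.timestamps.asi8 - pd.Timestamp(origin).value) / 3.6e12


@dataclass(frozen=True)
class Window:
    """Half-open time interval [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    def contains(self, ts) -> np.ndarray:
        ts = pd.DatetimeIndex(ts)
        return (ts >= self.start) & (ts < self.end)


@dataclass(frozen=True)
class DailySummary:
    date: pd.Timestamp  # UTC calendar day
    mean: float
    variance: float  # population variance of that day's records
    n: int


def _check_ranges(values: np.ndarray, channel: str) -> np.ndarray:
    """Boolean mask of rows passing the channel's validity checks."""
    lo, hi = RANGE_CHECKS.get(channel, (None, None))
    ok = np.isfinite(values)
    if lo is not None:
        ok &= values >= lo
    if hi is not None:
        ok &= values <= hi
    if channel == "head_moves":
        ok &= values == np.round(values)
    return ok


def read_series(path, channel: str, individual_id: str | None = None) -> TelemetrySeries:
    """Read one channel from a telemetry CSV.

    The file must have columns ``timestamp, individual_id, value`` (ISO-8601
    timestamps, UTF-8, header mandatory); a long-format file may carry an
    additional ``channel`` column, in which case only matching rows are used.
    Rows violating the channel's range checks are dropped and counted in the
    log; non-monotone timestamps raise.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "individual_id", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "channel" in df.columns:
        df = df[df["channel"] == channel]
    if individual_id is not None:
        df = df[df["individual_id"].astype(str) == str(individual_id)]
    ts = pd.to_datetime(df["timestamp"].to_numpy())
    vals = df["value"].to_numpy(dtype=float)
    ok = _check_ranges(vals, channel)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("read_series(%s, %s): dropped %d out-of-range rows", path, channel, n_drop)
    ids = df["individual_id"].astype(str).to_numpy()
    ind = ids[ok][0] if ok.any() else (individual_id or "")
    return TelemetrySeries(channel, ts[ok], vals[ok], individual_id=str(ind))


def write_series(series: TelemetrySeries, path) -> None:
    """Write a series to CSV so that ``read_series`` round-trips it exactly."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def slice_windows(
    series: TelemetrySeries, anchor, width_days: float
) -> list[tuple[Window, TelemetrySeries]]:
    """Cut a series into consecutive half-open windows of ``width_days``.

    Windows start at ``anchor`` and partition all records at or after it;
    a record exactly on a boundary belongs to the later window.  Empty
    windows inside the covered span are returned with zero-length series.
    """
    if width_days <= 0:
        raise ValueError("width_days must be positive")
    anchor = pd.Timestamp(anchor)
    width = pd.Timedelta(days=width_days)
    out: list[tuple[Window, TelemetrySeries]] = []
    if len(series) == 0:
        return out
    last = series.timestamps[-1]
    n_win = int(np.floor((last - anchor) / width)) + 1
    rel = ((series.timestamps.asi8 - anchor.value) / width.value).astype(np.int64)
    in_range = series.timestamps >= anchor
    for k in range(max(n_win, 0)):
        w = Window(anchor + k * width, anchor + (k + 1) * width, label=f"w{k:03d}")
        m = in_range & (rel == k)
        sub = TelemetrySeries(
            series.channel,
            series.timestamps[m],
            series.values[m],
            individual_id=series.individual_id,
            cadence_hint=series.cadence_hint,
        )
        out.append((w, sub))
    return out


def daily_stats(series: TelemetrySeries) -> list[DailySummary]:
    """Per-UTC-calendar-day mean, population variance and record count."""
    if len(series) == 0:
        return []
    df = pd.DataFrame({"value": series.values}, index=series.timestamps)
    g = df.groupby(df.index.floor("D"))["value"]
    out = []
    for day, vals in g:
        arr = vals.to_numpy()
        out.append(
            DailySummary(
                date=pd.Timestamp(day),
                mean=float(arr.mean()),
                variance=float(arr.var()),
                n=len(arr),
            )
        )
    return out


def daily_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    """Daily summaries as a DataFrame with columns date, mean, variance, n."""
    return pd.DataFrame(
        {
            "date": [s.date for s in summaries],
            "mean": [s.mean for s in summaries],
            "variance": [s.variance for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
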