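#!/usr/bin/env python
"""Mixed-model analysis of what drives diel rhythm power.

One random-intercept model per response channel: 15-day log mean
significant diel power against window means of daily radiation variance,
daily collar-temperature variance, and the fitted NDVI curve.  Writes one
standardized-coefficient table per channel.
"""

import argparse
from pathlib import Path

import pandas as pd

from reinrhythm import drivers, seasonal
from reinrhythm.core import Window, daily_frame, daily_stats, read_series


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--solar-dir", type=Path, default=Path("results/solar"))
    ap.add_argument("--rhythms-dir", type=Path, default=Path("results/rhythms"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/drivers"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    sol = pd.read_csv(args.solar_dir / "solar_days.csv", parse_dates=["date"])
    ndvi = read_series(args.data_dir / "ndvi.csv", "ndvi")
    nfit = seasonal.fit_ndvi_curve(ndvi, n_boot=0)
    wp = pd.read_csv(args.rhythms_dir / "windowed_power.csv", parse_dates=["window_start"])

    tcv = {}
    for p in sorted(args.data_dir.glob("*_t_collar.csv")):
        ind = p.name.split("_")[0]
        tcv[ind] = daily_frame(daily_stats(read_series(p, "t_collar")))

    for ch, sub in wp.groupby("channel"):
        power = {}
        for ind, g in sub.groupby("individual_id"):
            power[ind] = [
                (Window(row.window_start, row.window_start + pd.Timedelta(days=15)),
                 None if pd.isna(row.mean_power) else row.mean_power)
                for row in g.itertuples()
            ]
        rows = drivers.assemble_drivers(power, sol, tcv, nfit)
        if len(rows) < 10 or rows["individual_id"].nunique() < 2:
            print(f"{ch}: too few rows for the mixed model ({len(rows)})")
            continue
        fit = drivers.fit_mixed_model(rows)
        tab = drivers.report_table(fit)
        tab.to_csv(args.out_dir / f"drivers_{ch}.csv", index=False)
        print(f"\nresponse: log diel power of {ch} ({fit.n_rows} windows)")
        print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
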