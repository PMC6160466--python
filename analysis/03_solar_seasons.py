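#!/usr/bin/env python
"""Compute the solar zeitgeber and the photic/vegetation season calendar.

Writes the per-day solar table (elevation extrema, radiation variance,
light label) for the study year, fits the baseline cosine to the NDVI
composites, and segments the year into DD / LD / LL_low / LL_high.
"""

import argparse
from pathlib import Path

import pandas as pd

from reinrhythm import seasonal, solar
from reinrhythm.core import read_series

STUDY_START, STUDY_END = "2012-11-15", "2013-11-15"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/solar"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tab = solar.day_table(STUDY_START, STUDY_END)
    tab.to_csv(args.out_dir / "solar_days.csv", index=False)

    first_ll, last_ll, _, _ = solar.find_light_season_bounds(2013, solar.SITE_LAT_NORTH)
    print(
        f"continual civil daylight at {solar.SITE_LAT_NORTH}N: "
        f"{first_ll.date()} (doy {first_ll.dayofyear}) to {last_ll.date()} (doy {last_ll.dayofyear})"
    )

    ndvi = read_series(args.data_dir / "ndvi.csv", "ndvi")
    nfit = seasonal.fit_ndvi_curve(ndvi, n_boot=200, seed=0)
    crossing = seasonal.first_positive_crossing(nfit, 2013)
    print(f"fitted NDVI crosses zero on {crossing.date()}")
    days = pd.date_range(STUDY_START, STUDY_END, freq="D", inclusive="left")
    pd.DataFrame(
        {"date": days, "ndvi_fit": nfit.predict(days.dayofyear.to_numpy(dtype=float))}
    ).to_csv(args.out_dir / "ndvi_curve.csv", index=False)

    seasons = solar.segment_seasons(STUDY_START, STUDY_END, ndvi_crossing=crossing)
    seg = pd.DataFrame(seasons.segments, columns=["label", "start", "end"])
    seg.to_csv(args.out_dir / "seasons.csv", index=False)
    print("photic seasons:")
    for _, r in seg.iterrows():
        print(f"  {r['label']:8s} {r['start'].date()} - {r['end'].date()}")


if __name__ == "__main__":
    main()
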