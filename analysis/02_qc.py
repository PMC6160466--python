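#!/usr/bin/env python
"""Apply the sensor filters: four-step stationary heart rate and the rumen
temperature jump filter.

Reads the raw CSVs written by 01_simulate.py, writes filtered channel CSVs
and a per-animal QC report with removal counts per step.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reinrhythm import qc
from reinrhythm.core import read_series, write_series


def read_beats(path: Path):
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        iv = np.fromstring(row["intervals"], sep=" ") if isinstance(row["intervals"], str) else np.array([])
        out.append(qc.BeatWindow(start=pd.Timestamp(row["start"]), intervals=iv))
    return out


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    reports = []
    for beats_csv in sorted(args.data_dir.glob("*_beats.csv")):
        ind = beats_csv.name.replace("_beats.csv", "")
        activity = read_series(args.data_dir / f"{ind}_activity.csv", "activity")
        beats = read_beats(beats_csv)
        hr, rep = qc.stationary_heart_rate(beats, activity)
        write_series(hr, args.out_dir / f"{ind}_hr_stationary.csv")
        row = rep.to_frame()
        row.insert(0, "individual_id", ind)
        reports.append(row)

        trumen = read_series(args.data_dir / f"{ind}_t_rumen.csv", "t_rumen")
        filt = qc.filter_trumen(trumen)
        write_series(filt, args.out_dir / f"{ind}_t_rumen.csv")
        print(
            f"{ind}: {rep.n_kept}/{rep.n_total} heart-rate windows kept "
            f"(coverage -{rep.n_coverage_removed}, activity -{rep.n_active_removed}, "
            f"outlier -{rep.n_outlier_removed}); "
            f"rumen filter removed {len(trumen) - len(filt)} of {len(trumen)} records"
        )

    pd.concat(reports, ignore_index=True).to_csv(args.out_dir / "qc_report.csv", index=False)
    print(f"QC report written to {args.out_dir / 'qc_report.csv'}")


if __name__ == "__main__":
    main()
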