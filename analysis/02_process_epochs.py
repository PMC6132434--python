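#!/usr/bin/env python
"""Process raw epoch streams into daily records and per-person summaries.

Reintegrates to 60-s epochs, scans for non-wear (>= 60 min of zeros with up
to 2 min of interruptions), drops invalid days (< 10 h or > 16 h wear),
classifies wear minutes by the Evenson cut-points, and averages over valid
days.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, SCRATCH

from isosub import epochs


def main() -> None:
    stream_path = SCRATCH / "epoch_stream.csv"
    if not stream_path.exists():
        sys.exit("run 01_simulate_cohort.py first")
    series_list = epochs.read_epoch_stream(stream_path)
    print(f"processing {len(series_list)} person streams ...")

    all_days, summaries = [], []
    for series in series_list:
        days, summary = epochs.process_series(series)
        all_days.extend(days)
        summaries.append(summary)

    days_df = epochs.day_records_to_frame(all_days)
    summ_df = epochs.summaries_to_frame(summaries)
    days_df.to_csv(RESULTS / "day_records.csv", index=False)
    summ_df.to_csv(RESULTS / "activity_summaries.csv", index=False)

    n_valid = int(days_df["valid"].sum())
    print(f"{len(days_df)} person-days: {n_valid} valid, "
          f"{len(days_df) - n_valid} excluded by the 10-16 h wear rule")
    print(f"{len(summ_df)} persons retained (>= 1 valid day)")
    print("\nmean daily minutes over valid days:")
    print(summ_df[["mean_wear", "mean_sedentary", "mean_lpa", "mean_mvpa",
                   "cpm"]].mean().round(1).to_string())
    print(f"\nwrote {RESULTS / 'day_records.csv'} and "
          f"{RESULTS / 'activity_summaries.csv'}")


if __name__ == "__main__":
    main()
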