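"""Accelerometer epoch processing.

Turns raw epoch-level activity-count streams into per-person daily activity
summaries: reintegration to 60-s epochs, non-wear detection (runs of >=60 min
of zeros allowing up to 2 min of non-zero interruptions), wear-time validity
(>=10 h and <=16 h per day), count cut-point intensity classification
(sedentary / light / moderate-to-vigorous), and per-day / per-person
averaging over valid days.

The processing conventions follow the harmonised reanalysis used by the
pooled ICAD (International Children's Accelerometry Database) studies; the
default intensity cut-points are the Evenson youth thresholds (sedentary
<= 100 counts/min, MVPA >= 2296 counts/min), supplied as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError, StructuralError

__all__ = [
    "EpochSeries",
    "WearInterval",
    "IntensityThresholds",
    "DayRecord",
    "PersonActivitySummary",
    "EpochConfig",
    "reintegrate",
    "detect_nonwear",
    "nonwear_mask",
    "classify_epoch",
    "classify_counts",
    "summarize_day",
    "summarize_person",
    "process_series",
    "read_epoch_stream",
    "write_epoch_stream",
    "day_records_to_frame",
    "summaries_to_frame",
]

SEDENTARY, LPA, MVPA = "sedentary", "lpa", "mvpa"

#: Fixed, documented column orders for delimited output.
DAY_COLUMNS = [
    "person_id", "date", "wear_minutes", "sedentary_minutes", "lpa_minutes",
    "mvpa_minutes", "total_counts", "valid",
]
SUMMARY_COLUMNS = [
    "person_id", "n_valid_days", "mean_wear", "mean_sedentary", "mean_lpa",
    "mean_mvpa", "cpm",
]


@dataclass(frozen=True)
class IntensityThresholds:
    """Count cut-points (counts per 60-s epoch) separating intensity bands.

    An epoch is sedentary iff counts <= ``sedentary_max``, light iff
    ``sedentary_max`` < counts <= ``light_max``, and MVPA iff counts >
    ``light_max``.  Defaults are the Evenson youth cut-points; upper-edge
    inclusivity (``<=``) is this package's convention.
    """

    sedentary_max: int = 100
    light_max: int = 2295

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.light_max):
            raise ConfigurationError(
                f"thresholds must satisfy 0 <= sedentary_max < light_max, "
                f"got ({self.sedentary_max}, {self.light_max})"
            )


@dataclass(frozen=True)
class EpochConfig:
    """All epoch-processing knobs, in the units the rules are stated in."""

    target_epoch: int = 60          # seconds
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    min_window: int = 60            # minutes of zeros for a non-wear run
    max_interrupt: int = 2          # non-zero minutes tolerated inside a run
    min_wear: int = 600             # minutes; valid day lower bound (10 h)
    max_wear: int = 960             # minutes; valid day upper bound (16 h)
    min_valid_days: int = 1

    def __post_init__(self) -> None:
        if self.target_epoch <= 0:
            raise ConfigurationError("target_epoch must be a positive number of seconds")
        if self.min_window <= 0 or self.max_interrupt < 0:
            raise ConfigurationError("min_window must be positive and max_interrupt non-negative")
        if not (0 < self.min_wear <= self.max_wear <= 1440):
            raise ConfigurationError("need 0 < min_wear <= max_wear <= 1440 minutes")
        if self.min_valid_days < 1:
            raise ConfigurationError("min_valid_days must be >= 1")


@dataclass
class EpochSeries:
    """One person's ordered activity-count stream at a fixed epoch length."""

    person_id: str
    epoch_length: int                      # seconds; positive divisor of 60
    timestamps: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or 60 % self.epoch_length:
            raise ConfigurationError(
                f"epoch_length must be a positive divisor of 60 s, got {self.epoch_length}"
            )
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.timestamps) != len(self.counts):
            raise InputError("timestamps and counts differ in length")
        if np.any(self.counts < 0):
            bad = self.timestamps[int(np.argmax(self.counts < 0))]
            raise InputError(f"negative counts at {bad}")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise StructuralError("timestamps are not strictly increasing")
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps.asi8)
            if np.any(diffs <= 0):
                raise StructuralError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.counts)

    def days(self) -> Iterator["EpochSeries"]:
        """Split at calendar-day (midnight) boundaries, in order."""
        if len(self) == 0:
            return
        dates = self.timestamps.normalize()
        for day in dates.unique():
            sel = dates == day
            yield EpochSeries(self.person_id, self.epoch_length,
                              self.timestamps[sel], self.counts[sel])


@dataclass(frozen=True)
class WearInterval:
    start: pd.Timestamp
    end: pd.Timestamp          # exclusive
    status: str                # "wear" | "nonwear"


@dataclass(frozen=True)
class DayRecord:
    person_id: str
    date: pd.Timestamp
    wear_minutes: int
    sedentary_minutes: int
    lpa_minutes: int
    mvpa_minutes: int
    total_counts: int
    valid: bool


@dataclass(frozen=True)
class PersonActivitySummary:
    person_id: str
    n_valid_days: int
    mean_wear: float
    mean_sedentary: float
    mean_lpa: float
    mean_mvpa: float
    cpm: float


# ---------------------------------------------------------------------------
# reintegration

def reintegrate(series: EpochSeries, target_epoch: int = 60) -> EpochSeries:
    """Sum consecutive epochs into ``target_epoch``-second blocks.

    Requires a gap-free stream whose epochs align to ``target_epoch``
    boundaries within each calendar day; total counts are conserved.  Gaps
    raise :class:`StructuralError` naming the first offending timestamp
    rather than being zero-filled, which would manufacture sedentary time.
    """
    if target_epoch <= 0 or target_epoch % series.epoch_length:
        raise ConfigurationError(
            f"series epoch length {series.epoch_length}s does not divide "
            f"target epoch {target_epoch}s"
        )
    k = target_epoch // series.epoch_length
    out_ts, out_counts = [], []
    for day in series.days():
        diffs = np.diff(day.timestamps.asi8)
        expected = np.timedelta64(series.epoch_length, "s").astype("timedelta64[ns]").astype(np.int64)
        gap = np.flatnonzero(diffs != expected)
        if gap.size:
            raise StructuralError(
                f"gap in epoch stream after {day.timestamps[int(gap[0])]}"
            )
        offset_s = (day.timestamps[0] - day.timestamps[0].normalize()).total_seconds()
        if offset_s % target_epoch:
            raise StructuralError(
                f"epochs starting {day.timestamps[0]} are not aligned to "
                f"{target_epoch}-s boundaries"
            )
        if len(day) % k:
            raise StructuralError(
                f"day starting {day.timestamps[0]} has {len(day)} epochs, "
                f"not a multiple of {k}"
            )
        blocks = day.counts.reshape(-1, k).sum(axis=1)
        out_counts.append(blocks)
        out_ts.append(day.timestamps[::k])
    if not out_ts:
        return EpochSeries(series.person_id, target_epoch,
                           pd.DatetimeIndex([]), np.empty(0, dtype=np.int64))
    return EpochSeries(
        series.person_id, target_epoch,
        pd.DatetimeIndex(np.concatenate([t.values for t in out_ts])),
        np.concatenate(out_counts),
    )


# ---------------------------------------------------------------------------
# non-wear detection

def nonwear_mask(counts: np.ndarray, min_window: int = 60,
                 max_interrupt: int = 2) -> np.ndarray:
    """Boolean mask of non-wear epochs for one day of 60-s counts.

    An epoch is non-wear iff it lies inside some window of >= ``min_window``
    epochs containing at most ``max_interrupt`` non-zero epochs, where the
    window starts and ends on zero epochs.  Linear-time two-pointer scan:
    for every zero start the furthest admissible end is found, and the union
    of all admissible maximal windows is marked.
    """
    counts = np.asarray(counts)
    n = len(counts)
    mask = np.zeros(n, dtype=bool)
    if n < min_window:
        return mask
    nz = counts > 0
    # last zero-epoch index at or before each position
    last_zero = np.where(~nz, np.arange(n), -1)
    np.maximum.accumulate(last_zero, out=last_zero)
    diff = np.zeros(n + 1, dtype=np.int64)
    j = -1          # right edge of current window
    interrupts = 0  # non-zero epochs in counts[i..j]
    for i in range(n):
        if j < i:
            j, interrupts = i, int(nz[i])
        if nz[i]:
            interrupts -= 1  # will leave the window when i advances
            continue
        while j + 1 < n and interrupts + nz[j + 1] <= max_interrupt:
            j += 1
            interrupts += int(nz[j])
        end = last_zero[j]   # run must close on a zero epoch
        if end - i + 1 >= min_window:
            diff[i] += 1
            diff[end + 1] -= 1
    np.cumsum(diff[:-1], out=diff[:-1])
    return diff[:-1] > 0


def detect_nonwear(series: EpochSeries, min_window: int = 60,
                   max_interrupt: int = 2) -> list[WearInterval]:
    """Partition each recorded day into alternating wear/non-wear intervals."""
    if series.epoch_length != 60:
        raise ConfigurationError(
            f"non-wear detection requires 60-s epochs, got {series.epoch_length}s"
        )
    intervals: list[WearInterval] = []
    step = pd.Timedelta(seconds=60)
    for day in series.days():
        mask = nonwear_mask(day.counts, min_window, max_interrupt)
        if len(mask) == 0:
            continue
        edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(mask)]])
        for s, e in zip(starts, ends):
            intervals.append(WearInterval(
                start=day.timestamps[s],
                end=day.timestamps[e - 1] + step,
                status="nonwear" if mask[s] else "wear",
            ))
    return intervals


# ---------------------------------------------------------------------------
# intensity classification

def classify_counts(counts: np.ndarray,
                    thresholds: IntensityThresholds) -> np.ndarray:
    """Vector intensity codes: 0 sedentary, 1 light, 2 MVPA."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise InputError("negative counts cannot be classified")
    return np.where(counts <= thresholds.sedentary_max, 0,
                    np.where(counts <= thresholds.light_max, 1, 2))


def classify_epoch(counts: int, thresholds: IntensityThresholds) -> str:
    """Intensity band of a single 60-s epoch count value."""
    code = int(classify_counts(np.asarray([counts]), thresholds)[0])
    return (SEDENTARY, LPA, MVPA)[code]


# ---------------------------------------------------------------------------
# daily and per-person summaries

def summarize_day(series: EpochSeries, nonwear: Sequence[WearInterval],
                  thresholds: IntensityThresholds,
                  min_wear: int = 600, max_wear: int = 960) -> DayRecord:
    """Tally one day's wear time and intensity minutes.

    ``series`` must hold a single calendar day at 60-s epochs; ``nonwear``
    are the intervals detected from the same stream.  Intensity minutes are
    computed over wear epochs only, so sedentary + LPA + MVPA == wear
    exactly.  A day is valid iff ``min_wear <= wear_minutes <= max_wear``.
    """
    if series.epoch_length != 60:
        raise ConfigurationError("daily summaries require 60-s epochs")
    date = series.timestamps[0].normalize() if len(series) else pd.NaT
    wear = np.ones(len(series), dtype=bool)
    for iv in nonwear:
        if iv.status != "nonwear":
            continue
        sel = (series.timestamps >= iv.start) & (series.timestamps < iv.end)
        wear[np.asarray(sel)] = False
    codes = classify_counts(series.counts[wear], thresholds)
    wear_minutes = int(wear.sum())
    return DayRecord(
        person_id=series.person_id,
        date=date,
        wear_minutes=wear_minutes,
        sedentary_minutes=int((codes == 0).sum()),
        lpa_minutes=int((codes == 1).sum()),
        mvpa_minutes=int((codes == 2).sum()),
        total_counts=int(series.counts[wear].sum()),
        valid=bool(min_wear <= wear_minutes <= max_wear),
    )


def summarize_person(days: Sequence[DayRecord],
                     min_valid_days: int = 1) -> Optional[PersonActivitySummary]:
    """Average daily summaries over valid days; ``None`` below the day floor.

    cpm is the per-day ratio total wear counts / wear minutes, averaged over
    valid days.
    """
    if not days:
        return None
    person_ids = {d.person_id for d in days}
    if len(person_ids) != 1:
        raise InputError(f"days span multiple persons: {sorted(person_ids)}")
    valid = [d for d in days if d.valid]
    if len(valid) < min_valid_days:
        return None
    n = len(valid)
    return PersonActivitySummary(
        person_id=days[0].person_id,
        n_valid_days=n,
        mean_wear=sum(d.wear_minutes for d in valid) / n,
        mean_sedentary=sum(d.sedentary_minutes for d in valid) / n,
        mean_lpa=sum(d.lpa_minutes for d in valid) / n,
        mean_mvpa=sum(d.mvpa_minutes for d in valid) / n,
        cpm=sum(d.total_counts / d.wear_minutes for d in valid if d.wear_minutes) / n,
    )


def process_series(series: EpochSeries,
                   config: EpochConfig = EpochConfig()
                   ) -> tuple[list[DayRecord], Optional[PersonActivitySummary]]:
    """Full per-person pipeline: reintegrate, scan non-wear, tally, average."""
    series = reintegrate(series, config.target_epoch)
    days = []
    for day in series.days():
        nw = detect_nonwear(day, config.min_window, config.max_interrupt)
        days.append(summarize_day(day, nw, config.thresholds,
                                  config.min_wear, config.max_wear))
    return days, summarize_person(days, config.min_valid_days)


# ---------------------------------------------------------------------------
# delimited I/O

def read_epoch_stream(path) -> list[EpochSeries]:
    """Read a comma-delimited epoch file (person_id, timestamp, counts)."""
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = {"person_id", "timestamp", "counts"} - set(df.columns)
    if missing:
        raise InputError(f"epoch file {path} lacks columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for pid, grp in df.groupby("person_id", sort=True):
        ts = pd.DatetimeIndex(grp["timestamp"])
        if len(ts) > 1:
            steps = np.diff(ts.asi8) // 10**9
            epoch_length = int(steps.min())
        else:
            epoch_length = 60
        out.append(EpochSeries(str(pid), epoch_length, ts,
                               grp["counts"].to_numpy()))
    return out


def write_epoch_stream(series_list: Iterable[EpochSeries], path) -> None:
    frames = [
        pd.DataFrame({"person_id": s.person_id,
                      "timestamp": s.timestamps,
                      "counts": s.counts})
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def day_records_to_frame(days: Iterable[DayRecord]) -> pd.DataFrame:
    rows = [{c: getattr(d, c if c != "date" else "date") for c in DAY_COLUMNS}
            for d in days]
    df = pd.DataFrame(rows, columns=DAY_COLUMNS)
    if len(df):
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def summaries_to_frame(summaries: Iterable[Optional[PersonActivitySummary]]) -> pd.DataFrame:
    rows = [{c: getattr(s, c) for c in SUMMARY_COLUMNS}
            for s in summaries if s is not None]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
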