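"""Device-export reading and preprocessing into 2-day fit windows.

Pipeline: raw timestamped records -> 5-min binned series -> consolidated
sleep periods -> wake "days" (wake spans separated by sleeps longer than
2 h) -> 2-day fit windows centred at the sleep period in between, each
holding only awake bins with an observed heart rate.

All timestamps are handled in the device's local civil time; model time
``t`` is hours since local midnight of a window's first day.  Daylight-
saving transitions pass through as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GapSeries

__all__ = [
    "RawRecordSet",
    "BinnedSeries",
    "SleepPeriod",
    "WakeDay",
    "FitWindow",
    "read_device_export",
    "bin_records",
    "consolidate_sleep",
    "infer_sleep_from_gaps",
    "segment_wake_days",
    "build_fit_windows",
    "prepare_windows",
    "window_manifest",
]

log = logging.getLogger(__name__)

DIALECTS = ("generic", "fitbit_split", "applewatch")

HR_BPM_MIN, HR_BPM_MAX = 20.0, 250.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecordSet:
    """Merged per-subject device records, sorted by time.

    hr : Series of bpm indexed by timestamp
    steps : Series of step counts (over each record's native interval)
        indexed by timestamp
    sleep_intervals : list of (start, end) device-labelled sleep
    """

    hr: pd.Series
    steps: pd.Series
    sleep_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self):
        self.hr = self.hr.sort_index()
        self.steps = self.steps.sort_index()
        self.sleep_intervals = sorted(self.sleep_intervals, key=lambda iv: iv[0])
        if len(self.hr) and not ((self.hr > HR_BPM_MIN) & (self.hr < HR_BPM_MAX)).all():
            bad = int(((self.hr <= HR_BPM_MIN) | (self.hr >= HR_BPM_MAX)).sum())
            log.warning("dropping %d HR records outside (%g, %g) bpm", bad, HR_BPM_MIN, HR_BPM_MAX)
            self.hr = self.hr[(self.hr > HR_BPM_MIN) & (self.hr < HR_BPM_MAX)]
        if len(self.steps) and (self.steps < 0).any():
            raise ValueError("negative step counts")


@dataclass
class BinnedSeries:
    """HR/steps/wake series on a fixed 5-min grid with explicit missingness.

    hr is NaN wherever no HR record fell in the bin (never zero-filled);
    awake is False for every bin overlapping a consolidated sleep period.
    """

    bin_start: pd.DatetimeIndex
    hr: np.ndarray
    steps_per_min: np.ndarray
    awake: np.ndarray
    bin_minutes: float = 5.0

    def __post_init__(self):
        n = len(self.bin_start)
        self.hr = np.asarray(self.hr, dtype=float)
        self.steps_per_min = np.asarray(self.steps_per_min, dtype=float)
        self.awake = np.asarray(self.awake, dtype=bool)
        if not (len(self.hr) == len(self.steps_per_min) == len(self.awake) == n):
            raise ValueError("field lengths differ")

    def __len__(self):
        return len(self.bin_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "hr": self.hr,
                "steps_per_min": self.steps_per_min,
                "awake": self.awake,
            }
        )

    def to_records(self) -> RawRecordSet:
        """Re-express the binned series as raw records (used to check that
        binning is idempotent: step counts become bin totals at bin starts)."""
        m = ~np.isnan(self.hr)
        hr = pd.Series(self.hr[m], index=self.bin_start[m])
        steps = pd.Series(self.steps_per_min * self.bin_minutes, index=self.bin_start)
        return RawRecordSet(hr=hr, steps=steps, sleep_intervals=[])


@dataclass(frozen=True)
class SleepPeriod:
    """One consolidated sleep period; wake gaps < 2 h inside it are absorbed."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("sleep period must have end > start")

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def midpoint_hour(self) -> float:
        """Clock hour of the midpoint, in [0, 24)."""
        m = self.midpoint
        return m.hour + m.minute / 60.0 + m.second / 3600.0


@dataclass
class WakeDay:
    """A wake span bounded by sleeps longer than 2 h (or record boundaries)."""

    start: pd.Timestamp
    end: pd.Timestamp
    bins: np.ndarray  # indices into the BinnedSeries, awake bins only
    bounded_left: bool = True
    bounded_right: bool = True


@dataclass
class FitWindow:
    """One 2-day interval centred at a sleep period: the unit of one fit."""

    day_before: WakeDay
    day_after: WakeDay
    center_sleep: SleepPeriod
    t: np.ndarray       # hours since local midnight of day 1
    hr: np.ndarray      # bpm
    steps_per_min: np.ndarray
    bin_minutes: float = 5.0

    @property
    def n_obs(self) -> int:
        return len(self.t)

    @property
    def day1_date(self):
        return self.day_before.start.normalize()

    def to_gap_series(self) -> GapSeries:
        return GapSeries(self.t, self.hr, self.steps_per_min, self.bin_minutes)


# ---------------------------------------------------------------------------
# reading device exports
# ---------------------------------------------------------------------------

def _parse_clean(df: pd.DataFrame, ts_col: str, val_cols: Sequence[str], path) -> pd.DataFrame:
    """Coerce timestamp/value columns; drop and count malformed rows."""
    n0 = len(df)
    df = df.copy()
    df[ts_col] = pd.to_datetime(df[ts_col], errors="coerce")
    for c in val_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=[ts_col])
    n_bad = n0 - len(df)
    if n_bad:
        log.warning("%s: skipped %d malformed row(s) of %d", path, n_bad, n0)
    return df


def _read_generic(paths: Iterable[Path]) -> RawRecordSet:
    hr_parts, step_parts, starts, ends = [], [], [], []
    for path in paths:
        df = pd.read_csv(path)
        df = _parse_clean(df, "timestamp", ["value"], path)
        df = df.dropna(subset=["value"]) if "value" in df else df
        for stream, sub in df.groupby("stream"):
            if stream == "hr":
                hr_parts.append(pd.Series(sub["value"].values, index=sub["timestamp"].values))
            elif stream == "steps":
                step_parts.append(pd.Series(sub["value"].values, index=sub["timestamp"].values))
            elif stream == "sleep_start":
                starts.extend(sub["timestamp"].tolist())
            elif stream == "sleep_end":
                ends.extend(sub["timestamp"].tolist())
            else:
                log.warning("%s: unknown stream %r ignored (%d rows)", path, stream, len(sub))
    sleeps = list(zip(sorted(starts), sorted(ends)))
    return RawRecordSet(
        hr=pd.concat(hr_parts) if hr_parts else pd.Series(dtype=float),
        steps=pd.concat(step_parts) if step_parts else pd.Series(dtype=float),
        sleep_intervals=sleeps,
    )


def _classify_fitbit(paths: Iterable[Path]):
    hr_path = step_path = sleep_path = None
    for p in paths:
        name = Path(p).name.lower()
        if "sleep" in name:
            sleep_path = p
        elif "step" in name:
            step_path = p
        elif "hr" in name or "heart" in name:
            hr_path = p
    return hr_path, step_path, sleep_path


def _read_fitbit_split(paths: Iterable[Path]) -> RawRecordSet:
    hr_path, step_path, sleep_path = _classify_fitbit(paths)
    hr = pd.Series(dtype=float)
    steps = pd.Series(dtype=float)
    sleeps: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    if hr_path is not None:
        df = pd.read_csv(hr_path)
        ts, val = df.columns[:2]
        df = _parse_clean(df, ts, [val], hr_path).dropna(subset=[val])
        hr = pd.Series(df[val].values, index=df[ts].values)
    if step_path is not None:
        df = pd.read_csv(step_path)
        ts, val = df.columns[:2]
        df = _parse_clean(df, ts, [val], step_path).dropna(subset=[val])
        steps = pd.Series(df[val].values, index=df[ts].values)
    if sleep_path is not None:
        df = pd.read_csv(sleep_path)
        if len(df):
            start_c, end_c, stage_c = df.columns[:3]
            df = _parse_clean(df, start_c, [], sleep_path)
            df[end_c] = pd.to_datetime(df[end_c], errors="coerce")
            df = df.dropna(subset=[end_c])
            # any non-wake stage counts as sleep
            df = df[~df[stage_c].astype(str).str.lower().isin(["wake", "awake"])]
            sleeps = list(zip(df[start_c], df[end_c]))
    return RawRecordSet(hr=hr, steps=steps, sleep_intervals=sleeps)


def _read_applewatch(paths: Iterable[Path]) -> RawRecordSet:
    hr_parts, step_parts = [], []
    for path in paths:
        df = pd.read_csv(path)
        df = _parse_clean(df, "timestamp", ["hr", "steps"], path)
        h = df.dropna(subset=["hr"])
        s = df.dropna(subset=["steps"])
        hr_parts.append(pd.Series(h["hr"].values, index=h["timestamp"].values))
        step_parts.append(pd.Series(s["steps"].values, index=s["timestamp"].values))
    return RawRecordSet(
        hr=pd.concat(hr_parts) if hr_parts else pd.Series(dtype=float),
        steps=pd.concat(step_parts) if step_parts else pd.Series(dtype=float),
        sleep_intervals=[],
    )


def read_device_export(paths, dialect: str = "generic") -> RawRecordSet:
    """Read one subject's export files under the named dialect.

    ``generic``: CSV with columns timestamp, stream ({hr, steps,
    sleep_start, sleep_end}), value.  ``fitbit_split``: three CSVs (HR,
    Step, Sleep_Stage) identified by filename.  ``applewatch``: single CSV
    (timestamp, hr, steps) with no sleep column.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    paths = [Path(p) for p in (paths if not isinstance(paths, (str, Path)) else [paths])]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    reader = {"generic": _read_generic, "fitbit_split": _read_fitbit_split,
              "applewatch": _read_applewatch}[dialect]
    return reader(paths)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_records(records: RawRecordSet, bin_minutes: int = 5,
                sleeps: Sequence[SleepPeriod] | None = None) -> BinnedSeries:
    """Average HR and total steps into fixed bins (default 5 min).

    HR per bin is the arithmetic mean of the records falling in
    [bin_start, bin_start + bin); bins without an HR record are missing
    (NaN).  Step records are apportioned pro-rata by overlap of their
    native interval with each bin, so totals are conserved exactly.
    Averaging into bins keeps periods of more frequent measurement from
    disproportionately affecting the fit.
    """
    if 60 % bin_minutes:
        raise ValueError("bin_minutes must divide 60")
    bin_td = pd.Timedelta(minutes=bin_minutes)
    stamps = []
    if len(records.hr):
        stamps += [records.hr.index[0], records.hr.index[-1]]
    if len(records.steps):
        stamps += [records.steps.index[0], records.steps.index[-1]]
    for s, e in records.sleep_intervals:
        stamps += [s, e]
    if not stamps:
        idx = pd.DatetimeIndex([])
        z = np.zeros(0)
        return BinnedSeries(idx, z, z, z.astype(bool), float(bin_minutes))
    # native step interval: median spacing of the stream (each record is
    # taken to cover [t, t + native) and split pro-rata across bins)
    native = float(bin_minutes) * 60.0
    if len(records.steps) > 1:
        native = max(float(np.median(np.diff(records.steps.index.asi8)) / 1e9), 1.0)
    if len(records.steps):
        # cover the last record's native interval (half-open, hence the -1 ns)
        stamps.append(records.steps.index[-1]
                      + pd.Timedelta(seconds=native) - pd.Timedelta(1, "ns"))
    t0 = min(stamps).floor(bin_td)
    t1 = max(stamps).floor(bin_td)
    grid = pd.date_range(t0, t1, freq=bin_td)
    n = len(grid)

    hr = np.full(n, np.nan)
    if len(records.hr):
        means = records.hr.groupby(records.hr.index.floor(bin_td)).mean()
        pos = ((means.index - t0) // bin_td).astype(int)
        hr[pos] = means.values

    step_tot = np.zeros(n)
    if len(records.steps):
        ts = records.steps.index
        counts = records.steps.values.astype(float)
        start_s = (ts.asi8 - t0.value) / 1e9
        end_s = start_s + native
        bin_s = bin_minutes * 60.0
        first_bin = np.floor(start_s / bin_s).astype(int)
        max_span = int(np.ceil(native / bin_s)) + 1
        for j in range(max_span):
            b = first_bin + j
            lo = np.maximum(start_s, b * bin_s)
            hi = np.minimum(end_s, (b + 1) * bin_s)
            frac = np.clip(hi - lo, 0.0, None) / native
            ok = (frac > 0) & (b >= 0) & (b < n)
            np.add.at(step_tot, b[ok], counts[ok] * frac[ok])

    awake = np.ones(n, dtype=bool)
    if sleeps:
        awake = _awake_mask(grid, bin_td, sleeps)
    return BinnedSeries(grid, hr, step_tot / bin_minutes, awake, float(bin_minutes))


def _awake_mask(grid: pd.DatetimeIndex, bin_td, sleeps: Sequence[SleepPeriod]) -> np.ndarray:
    awake = np.ones(len(grid), dtype=bool)
    ends = grid + bin_td
    for sp in sleeps:
        awake &= ~((grid < sp.end) & (ends > sp.start))
    return awake


# ---------------------------------------------------------------------------
# sleep consolidation and wake-day segmentation
# ---------------------------------------------------------------------------

def consolidate_sleep(sleep_intervals, max_interruption_hours: float = 2.0) -> list[SleepPeriod]:
    """Merge sleep intervals separated by wake gaps shorter than 2 h.

    Short interruptions in the middle of longer sleep are absorbed into a
    single sleep period; the gap's data is later excluded from fitting.
    A gap of exactly ``max_interruption_hours`` is kept (strict reading of
    "less than two hours").
    """
    ivs = sorted(((pd.Timestamp(s), pd.Timestamp(e)) for s, e in sleep_intervals),
                 key=lambda iv: iv[0])
    gap_td = pd.Timedelta(hours=max_interruption_hours)
    out: list[list[pd.Timestamp]] = []
    for s, e in ivs:
        if e <= s:
            log.warning("dropping degenerate sleep interval %s–%s", s, e)
            continue
        if out and s < out[-1][1]:
            log.warning("overlapping sleep intervals at %s; merging", s)
            out[-1][1] = max(out[-1][1], e)
        elif out and s - out[-1][1] < gap_td:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [SleepPeriod(s, e) for s, e in out]


def infer_sleep_from_gaps(records: RawRecordSet, min_gap_hours: float = 4.0) -> list[SleepPeriod]:
    """Treat long no-data gaps as sleep separators when no sleep labels exist.

    Apple-Watch-style exports carry no sleep column but leave overnight
    charging gaps; a gap >= ``min_gap_hours`` between consecutive HR records
    with no steps recorded inside it is taken as a sleep period.
    """
    if len(records.hr) < 2:
        return []
    ts = records.hr.index
    gaps = np.diff(ts.asi8) / 3.6e12  # hours
    out = []
    for i in np.nonzero(gaps >= min_gap_hours)[0]:
        s, e = ts[i], ts[i + 1]
        in_gap = records.steps[(records.steps.index > s) & (records.steps.index < e)]
        if in_gap.sum() == 0:
            out.append(SleepPeriod(s, e))
    return out


def segment_wake_days(binned: BinnedSeries, sleeps: Sequence[SleepPeriod],
                      min_separator_hours: float = 2.0) -> list[WakeDay]:
    """Cut the record into wake "days" at sleeps longer than 2 h.

    Sleeps of exactly ``min_separator_hours`` or less (naps) do not split a
    day, but their bins are still excluded from every WakeDay.  Spans at the
    record boundaries are flagged unbounded.
    """
    if len(binned) == 0:
        return []
    bin_td = pd.Timedelta(minutes=binned.bin_minutes)
    awake = _awake_mask(binned.bin_start, bin_td, sleeps) if sleeps else np.ones(len(binned), bool)
    seps = [sp for sp in sleeps if sp.duration_hours > min_separator_hours]
    edges = [(binned.bin_start[0], False)]
    for sp in seps:
        edges.append((sp.start, True))
        edges.append((sp.end, True))
    edges.append((binned.bin_start[-1] + bin_td, False))
    days = []
    for i in range(0, len(edges) - 1, 2):
        start, left_ok = edges[i]
        end, right_ok = edges[i + 1]
        if end <= start:
            continue
        idx = np.nonzero(
            (binned.bin_start >= start) & (binned.bin_start + bin_td <= end) & awake
        )[0]
        day = WakeDay(start, end, idx, bounded_left=left_ok, bounded_right=right_ok)
        if not (left_ok and right_ok):
            log.debug("wake span %s–%s is unbounded on one side", start, end)
        days.append(day)
    if not seps:
        log.warning("no sleep longer than %g h; single unbounded wake span", min_separator_hours)
    return days


def build_fit_windows(days: Sequence[WakeDay], sleeps: Sequence[SleepPeriod],
                      binned: BinnedSeries, min_obs: int = 48) -> list[FitWindow]:
    """Pair flanking wake days around each interior sleep into fit windows.

    Observations keep only awake bins with an observed HR; windows with
    fewer than ``min_obs`` bins (default 48, ~4 h of data) are dropped.
    """
    seps = sorted((sp for sp in sleeps if sp.duration_hours > 2.0), key=lambda s: s.start)
    windows = []
    for day_b, day_a in zip(days[:-1], days[1:]):
        center = next((sp for sp in seps if sp.start >= day_b.end - pd.Timedelta(seconds=1)
                       and sp.end <= day_a.start + pd.Timedelta(seconds=1)), None)
        if center is None:
            continue
        if not (day_b.bounded_left and day_a.bounded_right):
            # only interior windows are fit
            log.debug("skipping boundary window at %s", center.midpoint)
            continue
        idx = np.concatenate([day_b.bins, day_a.bins])
        idx = idx[~np.isnan(binned.hr[idx])]
        if len(idx) < min_obs:
            log.info("window at %s dropped: %d obs < floor %d", center.midpoint, len(idx), min_obs)
            continue
        midnight = day_b.start.normalize()
        t = (binned.bin_start[idx] - midnight).total_seconds().values / 3600.0
        windows.append(FitWindow(day_b, day_a, center, t, binned.hr[idx],
                                 binned.steps_per_min[idx], binned.bin_minutes))
    return windows


def prepare_windows(records: RawRecordSet, bin_minutes: int = 5, min_obs: int = 48):
    """Full pipeline: returns (BinnedSeries, sleeps, wake days, fit windows).

    When the export carries no sleep labels, charging gaps >= 4 h with zero
    steps stand in as sleep separators.
    """
    intervals = records.sleep_intervals
    if intervals:
        sleeps = consolidate_sleep(intervals)
    else:
        sleeps = infer_sleep_from_gaps(records)
        if sleeps:
            log.info("no sleep labels; inferred %d sleep gaps from charging", len(sleeps))
    binned = bin_records(records, bin_minutes, sleeps=sleeps)
    days = segment_wake_days(binned, sleeps)
    windows = build_fit_windows(days, sleeps, binned, min_obs=min_obs)
    return binned, sleeps, days, windows


def window_manifest(windows: Sequence[FitWindow]) -> pd.DataFrame:
    """Tabular summary of fit windows (window_id, day1_date, midpoint, n_obs)."""
    return pd.DataFrame(
        {
            "window_id": range(len(windows)),
            "day1_date": [w.day1_date.date() for w in windows],
            "sleep_midpoint": [w.center_sleep.midpoint for w in windows],
            "n_obs": [w.n_obs for w in windows],
        }
    )
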