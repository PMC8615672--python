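"""Epoch sleep/wake scoring and nightly sleep summaries (TST, SE, WASO).

Scoring uses the weighted-moving-average rule of the Actiwatch device
family, adapted to 30-s epochs: the current epoch weighted 2, the one- and
two-epoch neighbours on each side weighted 1/5, the three- and four-epoch
neighbours 1/25; an epoch is scored wake when the weighted sum exceeds a
threshold (default 40, the device's medium setting).  Nightly rest
intervals come from diary bed/wake times (optionally snapped to the nearest
sustained activity change) or, without a diary, from the template-matching
phase markers.

Within each rest interval, sleep onset is the start of the first run of at
least 10 consecutive sleep-scored minutes; TST is sleep-scored time from
onset to the end of the interval, WASO the wake-scored time over the same
span, and SE = 100 * TST / interval duration.  Everything before onset is
latency, so latency + TST + WASO equals the interval duration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DiaryRecord, EpochSeries

__all__ = [
    "DEFAULT_KERNEL_30S",
    "DEFAULT_WAKE_THRESHOLD",
    "RestInterval",
    "NightSummary",
    "SleepSummary",
    "score_epochs",
    "resolve_rest_intervals",
    "summarize_sleep",
]

#: Weighted-moving-average kernel for 30-s epochs (centre weight 2,
#: +-1..2 epochs 1/5, +-3..4 epochs 1/25).
DEFAULT_KERNEL_30S = np.array(
    [1 / 25, 1 / 25, 1 / 5, 1 / 5, 2.0, 1 / 5, 1 / 5, 1 / 25, 1 / 25]
)
DEFAULT_WAKE_THRESHOLD = 40.0


def score_epochs(
    series: EpochSeries,
    threshold: float = DEFAULT_WAKE_THRESHOLD,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Label every epoch sleep (False) or wake (True).

    An epoch is wake iff the kernel-weighted sum of surrounding activity
    exceeds ``threshold``.  The series is zero-padded at its boundaries.
    """
    if threshold <= 0:
        raise ValueError("wake threshold must be positive")
    k = DEFAULT_KERNEL_30S if kernel is None else np.asarray(kernel, dtype=float)
    if k.size % 2 != 1:
        raise ValueError("kernel length must be odd")
    if k.size > series.n_epochs:
        raise ValueError("kernel longer than the series")
    weighted = np.convolve(series.activity, k[::-1], mode="same")
    return weighted > threshold


@dataclass
class RestInterval:
    """One night's in-bed interval."""

    night: int
    start: pd.Timestamp
    end: pd.Timestamp
    source: str = "diary"  # diary | auto | manual

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            self.end += pd.Timedelta(days=1)  # midnight wrap
        dur = (self.end - self.start).total_seconds()
        if not 0 < dur < 86400:
            raise ValueError("rest interval duration must be in (0, 24 h)")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def _epoch_index(series: EpochSeries, t: pd.Timestamp) -> int:
    return int(round((pd.Timestamp(t) - series.start).total_seconds() / series.epoch_length))


def _snap(series: EpochSeries, labels: np.ndarray, idx: int, window_epochs: int,
          to_sleep_start: bool) -> int:
    """Snap a diary time to the nearest sleep/wake transition within a window."""
    lo = max(0, idx - window_epochs)
    hi = min(series.n_epochs - 1, idx + window_epochs)
    if hi <= lo:
        return idx
    seg = labels[lo : hi + 1]
    # transitions wake->sleep (sustained drop) or sleep->wake (rise)
    d = np.diff(seg.astype(int))
    want = -1 if to_sleep_start else 1
    cands = np.nonzero(d == want)[0] + 1 + lo
    if cands.size == 0:
        return idx
    return int(cands[np.argmin(np.abs(cands - idx))])


def resolve_rest_intervals(
    series: EpochSeries,
    diary: DiaryRecord | None = None,
    snap_window_minutes: float = 0.0,
    labels: np.ndarray | None = None,
    auto_markers: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[RestInterval]:
    """Resolve one rest interval per night.

    Diary bed/wake times are used when present; with ``snap_window_minutes``
    > 0 they are snapped to the nearest sleep/wake transition of the scored
    ``labels`` within that window.  Without a diary, ``auto_markers`` —
    per-day (offset, onset) clock hours from the phase-marker stage — are
    used, pairing each evening offset with the following morning onset.
    """
    intervals: list[RestInterval] = []
    if diary is not None and diary.nights:
        win = int(round(snap_window_minutes * 60 / series.epoch_length))
        for k, night in enumerate(diary.nights):
            start, end = night.bedtime, night.waketime
            if win > 0 and labels is not None:
                i0 = _snap(series, labels, _epoch_index(series, start), win, True)
                i1 = _snap(series, labels, _epoch_index(series, end), win, False)
                times = series.epoch_times()
                start, end = times[min(i0, len(times) - 1)], times[min(i1, len(times) - 1)]
            intervals.append(RestInterval(night=k, start=start, end=end, source="diary"))
        return intervals
    if auto_markers is None:
        raise ValueError("need a diary or auto phase markers to place rest intervals")
    offsets, onsets = auto_markers
    # pair each evening offset (day k) with the next morning's onset (day k+1)
    first_midnight = series.epoch_times()[0].normalize() + pd.Timedelta(days=1)
    for k in range(len(offsets) - 1):
        if not (np.isfinite(offsets[k]) and np.isfinite(onsets[k + 1])):
            continue
        start = first_midnight + pd.Timedelta(days=k, hours=float(offsets[k]))
        end = first_midnight + pd.Timedelta(days=k + 1, hours=float(onsets[k + 1]))
        if end - start >= pd.Timedelta(days=1):
            end -= pd.Timedelta(days=1)
        if pd.Timedelta(0) < end - start < pd.Timedelta(days=1):
            intervals.append(RestInterval(night=k, start=start, end=end, source="auto"))
    return intervals


@dataclass
class NightSummary:
    night: int
    onset: pd.Timestamp | None
    latency_minutes: float
    tst_minutes: float
    waso_minutes: float
    efficiency: float
    interval_minutes: float
    valid: bool = True
    flag: str = ""


@dataclass
class SleepSummary:
    """Per-night summaries plus per-participant means over retained nights."""

    participant_id: str
    nights: list[NightSummary] = field(default_factory=list)

    @property
    def valid_nights(self) -> list[NightSummary]:
        return [n for n in self.nights if n.valid]

    def _mean(self, attr: str) -> float:
        vals = [getattr(n, attr) for n in self.valid_nights]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def tst(self) -> float:
        return self._mean("tst_minutes")

    @property
    def waso(self) -> float:
        return self._mean("waso_minutes")

    @property
    def efficiency(self) -> float:
        return self._mean("efficiency")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": self.participant_id,
                    "night": n.night,
                    "onset": n.onset,
                    "latency_min": n.latency_minutes,
                    "tst_min": n.tst_minutes,
                    "waso_min": n.waso_minutes,
                    "efficiency_pct": n.efficiency,
                    "interval_min": n.interval_minutes,
                    "valid": n.valid,
                    "flag": n.flag,
                }
                for n in self.nights
            ]
        )


def summarize_sleep(
    series: EpochSeries,
    labels: np.ndarray,
    intervals: list[RestInterval],
    onset_rule_minutes: float = 10.0,
) -> SleepSummary:
    """Compute nightly sleep onset, TST, WASO and SE from scored labels.

    Sleep onset is the start of the first run of ``onset_rule_minutes``
    consecutive sleep-scored minutes inside the interval; nights without
    such a run are flagged and omitted from the per-participant means.
    """
    epm = 60.0 / series.epoch_length  # epochs per minute
    run_needed = int(round(onset_rule_minutes * epm))
    out = SleepSummary(series.participant_id)
    times = series.epoch_times()
    for iv in intervals:
        i0 = max(0, _epoch_index(series, iv.start))
        i1 = min(series.n_epochs, _epoch_index(series, iv.end))
        if i1 - i0 < run_needed:
            out.nights.append(
                NightSummary(iv.night, None, 0, 0, 0, 0, iv.duration_minutes,
                             valid=False, flag="interval_outside_recording")
            )
            continue
        seg_wake = labels[i0:i1]
        onset_rel = _first_sleep_run(~seg_wake, run_needed)
        dur_min = (i1 - i0) / epm
        if onset_rel is None:
            out.nights.append(
                NightSummary(iv.night, None, dur_min, 0.0, 0.0, 0.0, dur_min,
                             valid=False, flag="no_sleep_onset")
            )
            continue
        latency = onset_rel / epm
        post = seg_wake[onset_rel:]
        waso = float(post.sum()) / epm
        tst = float((~post).sum()) / epm
        se = 100.0 * tst / dur_min
        out.nights.append(
            NightSummary(iv.night, times[i0 + onset_rel], latency, tst, waso, se, dur_min)
        )
    return out


def _first_sleep_run(sleep: np.ndarray, run: int) -> int | None:
    """Index of the first run of ``run`` consecutive True values, else None."""
    if run <= 1:
        hits = np.nonzero(sleep)[0]
        return int(hits[0]) if hits.size else None
    conv = np.convolve(sleep.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.nonzero(conv == run)[0]
    return int(hits[0]) if hits.size else None
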