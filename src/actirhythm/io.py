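"""Reading, validation, quality control and day alignment of epoch actigraphy.

Wrist actigraphs record movement counts in fixed epochs (30 s here).  This
module turns raw epoch CSV exports into validated :class:`EpochSeries`
objects, applies the study-style inclusion rules (at least five consecutive
complete 24-h days, daytime wear), and reshapes retained data into a
days x bins matrix (:class:`DayMatrix`) — the substrate of every downstream
rhythm computation.

Missing epochs are never imputed: a gap invalidates the containing day,
because the non-parametric rhythm statistics assume complete series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "DiaryRecord",
    "DiaryNight",
    "DayMatrix",
    "QCVerdict",
    "ActigraphyFormatError",
    "read_epoch_csv",
    "qc_inclusion",
    "trim_to_full_days",
]

SECONDS_PER_DAY = 86400


class ActigraphyFormatError(ValueError):
    """Raised for malformed epoch files (gaps, bad columns, negative counts)."""


@dataclass
class EpochSeries:
    """A uniformly sampled activity-count series anchored to local clock time.

    Parameters
    ----------
    participant_id : str
        Opaque identifier.
    start : pandas.Timestamp
        Local (naive) date-time of the first epoch.
    epoch_length : int
        Epoch duration in seconds; must divide 86400 evenly.
    activity : ndarray
        Non-negative counts, one per epoch.
    light : ndarray, optional
        Lux values, same length as ``activity``.
    off_wrist : ndarray of bool, optional
        True where the device was flagged off-wrist.
    """

    participant_id: str
    start: pd.Timestamp
    epoch_length: int
    activity: np.ndarray
    light: np.ndarray | None = None
    off_wrist: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1 or self.activity.size < 1:
            raise ValueError("activity must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity contains non-finite values")
        if np.any(self.activity < 0):
            raise ValueError("activity contains negative counts")
        if SECONDS_PER_DAY % int(self.epoch_length) != 0:
            raise ValueError(
                f"epoch_length {self.epoch_length} s does not divide 86400 evenly"
            )
        self.epoch_length = int(self.epoch_length)
        for name in ("light", "off_wrist"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.activity.shape:
                    raise ValueError(f"{name} length differs from activity")
                setattr(self, name, arr)
        if self.off_wrist is not None:
            self.off_wrist = self.off_wrist.astype(bool)

    @property
    def n_epochs(self) -> int:
        return self.activity.size

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    def epoch_times(self) -> pd.DatetimeIndex:
        """Timestamps of every epoch start."""
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=pd.Timedelta(seconds=self.epoch_length)
        )

    def clock_seconds(self) -> np.ndarray:
        """Seconds past local midnight for each epoch start."""
        start_sec = (
            self.start.hour * 3600 + self.start.minute * 60 + self.start.second
        )
        idx = np.arange(self.n_epochs, dtype=np.int64)
        return (start_sec + idx * self.epoch_length) % SECONDS_PER_DAY


@dataclass
class DiaryNight:
    """One diary night: reported bedtime/waketime plus optional annotations."""

    date: pd.Timestamp
    bedtime: pd.Timestamp
    waketime: pd.Timestamp
    n_wakings: int = 0
    nap_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        self.bedtime = pd.Timestamp(self.bedtime)
        self.waketime = pd.Timestamp(self.waketime)
        # midnight-wrap correction: a waketime at or before bedtime belongs
        # to the next calendar day
        if self.waketime <= self.bedtime:
            self.waketime += pd.Timedelta(days=1)
        naps = sorted(self.nap_intervals)
        for (a0, a1), (b0, b1) in zip(naps, naps[1:]):
            if b0 < a1:
                raise ValueError("nap intervals overlap within a night")
        self.nap_intervals = naps


@dataclass
class DiaryRecord:
    """Per-participant collection of diary nights."""

    participant_id: str
    nights: list[DiaryNight] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nights = sorted(self.nights, key=lambda n: n.bedtime)


@dataclass
class DayMatrix:
    """Rectangular D complete days x B bins-per-day array of mean activity.

    ``B = 2880`` for raw 30-s epochs, ``B = 24`` for hourly bins; any B that
    divides the epochs of a day is allowed.
    """

    participant_id: str
    values: np.ndarray
    day_start_clock_time: float = 0.0  # hours, [0, 24)
    first_day_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a D x B matrix with D >= 1")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("day matrix cells must be finite and non-negative")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def bins_per_day(self) -> int:
        return self.values.shape[1]

    @property
    def bin_hours(self) -> float:
        return 24.0 / self.bins_per_day

    def bin_clock_hours(self) -> np.ndarray:
        """Clock hour at the centre of each bin of a day."""
        b = self.bins_per_day
        return (self.day_start_clock_time + (np.arange(b) + 0.5) * 24.0 / b) % 24.0

    def rebin(self, bins_per_day: int) -> "DayMatrix":
        """Aggregate to coarser bins by arithmetic mean (conserves the grand mean)."""
        b = self.bins_per_day
        if b % bins_per_day != 0:
            raise ValueError(f"cannot rebin {b} bins into {bins_per_day}")
        f = b // bins_per_day
        vals = self.values.reshape(self.n_days, bins_per_day, f).mean(axis=2)
        return DayMatrix(
            self.participant_id, vals, self.day_start_clock_time, self.first_day_date
        )

    def flatten(self) -> np.ndarray:
        """Concatenated day-major series (no day-boundary reset)."""
        return self.values.reshape(-1)


DEFAULT_COLUMNS = {"timestamp": "timestamp", "activity": "activity",
                   "light": "lux", "off_wrist": "off_wrist"}


def read_epoch_csv(
    path,
    participant_id: str | None = None,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> EpochSeries:
    """Read an epoch-level actigraphy CSV into a validated :class:`EpochSeries`.

    The default dialect has a header row with columns ``timestamp``
    (ISO-8601 local), ``activity`` (integer counts), optional ``lux`` and
    ``off_wrist`` (0/1).  ``columns`` remaps logical names to vendor
    headers, e.g. ``{"activity": "Activity (counts)"}``.

    Raises
    ------
    ActigraphyFormatError
        If timestamps are not uniformly spaced (the first irregular pair is
        named), required columns are missing, or counts are negative.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, delimiter=delimiter)
    for logical in ("timestamp", "activity"):
        if colmap[logical] not in df.columns:
            raise ActigraphyFormatError(
                f"required column {colmap[logical]!r} missing from {path}"
            )
    ts = pd.to_datetime(df[colmap["timestamp"]])
    if len(ts) < 2:
        raise ActigraphyFormatError("need at least two epochs to infer epoch length")
    deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
    step = deltas[0]
    bad = np.nonzero(deltas != step)[0]
    if bad.size:
        i = int(bad[0])
        raise ActigraphyFormatError(
            f"non-uniform epoch spacing between rows {i + 1} and {i + 2}: "
            f"{deltas[i]:.0f} s vs expected {step:.0f} s"
        )
    if step <= 0 or SECONDS_PER_DAY % int(step) != 0:
        raise ActigraphyFormatError(f"epoch length {step} s does not divide a day")
    activity = pd.to_numeric(df[colmap["activity"]]).to_numpy(dtype=float)
    if np.any(activity < 0):
        raise ActigraphyFormatError("negative activity counts present")
    light = None
    if colmap["light"] in df.columns:
        light = pd.to_numeric(df[colmap["light"]]).to_numpy(dtype=float)
    off = None
    if colmap["off_wrist"] in df.columns:
        off = df[colmap["off_wrist"]].to_numpy().astype(bool)
    return EpochSeries(
        participant_id=participant_id or str(path),
        start=ts.iloc[0],
        epoch_length=int(step),
        activity=activity,
        light=light,
        off_wrist=off,
    )


def read_diary_csv(path, participant_id: str | None = None) -> dict[str, DiaryRecord]:
    """Read a diary CSV (``participant_id,date,bedtime,waketime,n_wakings,nap_intervals``).

    ``nap_intervals`` is a ``;``-separated list of ``HH:MM-HH:MM`` spans and
    may be empty.  Returns one :class:`DiaryRecord` per participant id.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    records: dict[str, DiaryRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        if participant_id is not None and pid != participant_id:
            continue
        date = pd.Timestamp(row["date"])
        bed = pd.Timestamp(f"{row['date']} {row['bedtime']}")
        wake = pd.Timestamp(f"{row['date']} {row['waketime']}")
        naps = []
        raw = row.get("nap_intervals", "")
        if isinstance(raw, str) and raw.strip():
            for span in raw.split(";"):
                a, b = span.split("-")
                naps.append(
                    (pd.Timestamp(f"{row['date']} {a}"), pd.Timestamp(f"{row['date']} {b}"))
                )
        night = DiaryNight(
            date=date, bedtime=bed, waketime=wake,
            n_wakings=int(row.get("n_wakings", 0) or 0), nap_intervals=naps,
        )
        records.setdefault(pid, DiaryRecord(pid, [])).nights.append(night)
    for rec in records.values():
        rec.nights.sort(key=lambda n: n.bedtime)
    return records


def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an :class:`EpochSeries` in the default epoch CSV dialect."""
    out = {"timestamp": series.epoch_times(), "activity": series.activity}
    if series.light is not None:
        out["lux"] = series.light
    if series.off_wrist is not None:
        out["off_wrist"] = series.off_wrist.astype(int)
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# day alignment

def _complete_day_slices(series: EpochSeries, day_start_hour: float) -> list[slice]:
    """Enumerate complete day windows [boundary, boundary + 1 day) in epochs."""
    ppd = series.epochs_per_day
    boundary_sec = int(round(day_start_hour * 3600)) % SECONDS_PER_DAY
    clock = series.clock_seconds()
    # first epoch exactly at the boundary
    starts = np.nonzero(clock == boundary_sec)[0]
    slices = []
    for s in starts:
        if s + ppd <= series.n_epochs:
            slices.append(slice(int(s), int(s + ppd)))
    # keep only consecutive, non-overlapping windows
    return [sl for sl in slices if (sl.start - (slices[0].start if slices else 0)) % ppd == 0]


def trim_to_full_days(
    series: EpochSeries,
    day_start_hour: float = 0.0,
    bins_per_day: int | None = None,
) -> DayMatrix:
    """Discard partial leading/trailing days and reshape to a D x B matrix.

    A day is complete if all of its epochs are present and none is flagged
    off-wrist (gaps are never imputed).  ``bins_per_day`` optionally rebins
    by arithmetic mean (e.g. 24 for hourly bins).

    Raises
    ------
    ValueError
        If no complete day exists from the chosen boundary.
    """
    slices = _complete_day_slices(series, day_start_hour)
    good = []
    for sl in slices:
        if series.off_wrist is not None and series.off_wrist[sl].any():
            continue
        good.append(sl)
    if not good:
        raise ValueError(
            f"no complete {day_start_hour:04.1f}h-aligned day in series "
            f"{series.participant_id!r}"
        )
    vals = np.stack([series.activity[sl] for sl in good])
    first_date = series.epoch_times()[good[0].start].normalize()
    dm = DayMatrix(series.participant_id, vals, day_start_hour, first_date)
    if bins_per_day is not None:
        dm = dm.rebin(bins_per_day)
    return dm


# ---------------------------------------------------------------------------
# quality control

@dataclass
class QCVerdict:
    """Inclusion verdict with machine-readable reason codes."""

    include: bool
    reasons: list[str]
    n_complete_days: int
    n_consecutive_days: int
    n_poor_wear_days: int
    flags: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.include


def _max_consecutive(indices: Sequence[int]) -> int:
    if not len(indices):
        return 0
    best = run = 1
    for a, b in zip(indices, list(indices)[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def qc_inclusion(
    series: EpochSeries,
    diary: DiaryRecord | None = None,
    min_consecutive_days: int = 5,
    day_start_hour: float = 0.0,
    daytime: tuple[float, float] = (8.0, 20.0),
    zero_run_minutes: float = 30.0,
    poor_wear_fraction: float = 0.20,
    max_poor_days: int = 1,
    dst_dates: Sequence[pd.Timestamp] = (),
) -> QCVerdict:
    """Apply the study inclusion rules and return a verdict with reason codes.

    Inclusion requires at least ``min_consecutive_days`` consecutive complete
    24-h days.  A day counts as poorly worn (night-only wear or extended
    removal) when more than ``poor_wear_fraction`` of its daytime
    (08:00-20:00 by default) epochs lie in zero-count runs of at least
    ``zero_run_minutes`` or are off-wrist flagged; more than ``max_poor_days``
    such days excludes the participant.  Recording windows covering a listed
    daylight-saving transition date raise a flag but never exclude on their
    own.
    """
    reasons: list[str] = []
    flags: list[str] = []
    slices = _complete_day_slices(series, day_start_hour)
    complete_idx = []
    for k, sl in enumerate(slices):
        if series.off_wrist is not None and series.off_wrist[sl].any():
            continue
        complete_idx.append(k)
    n_complete = len(complete_idx)
    n_consec = _max_consecutive(complete_idx)

    # night-only wear / extended removal detection on every recorded day
    run_len = int(round(zero_run_minutes * 60 / series.epoch_length))
    n_poor = 0
    clock = series.clock_seconds()
    day_sec0, day_sec1 = daytime[0] * 3600, daytime[1] * 3600
    in_window = (clock >= day_sec0) & (clock < day_sec1)
    nonwear = _zero_run_mask(series.activity, run_len)
    if series.off_wrist is not None:
        nonwear = nonwear | series.off_wrist
    for sl in slices:
        day_mask = np.zeros(series.n_epochs, bool)
        day_mask[sl] = True
        denom = (day_mask & in_window).sum()
        if denom == 0:
            continue
        frac = (day_mask & in_window & nonwear).sum() / denom
        if frac > poor_wear_fraction:
            n_poor += 1
    if n_poor > max_poor_days:
        reasons.append("night_only_wear")
    if n_consec < min_consecutive_days:
        reasons.append("insufficient_days")
    if dst_dates:
        times = series.epoch_times()
        span = pd.Interval(times[0].normalize(), times[-1].normalize(), closed="both")
        for d in dst_dates:
            if pd.Timestamp(d).normalize() in span:
                flags.append("dst_transition_in_window")
                break
    return QCVerdict(
        include=not reasons,
        reasons=reasons,
        n_complete_days=n_complete,
        n_consecutive_days=n_consec,
        n_poor_wear_days=n_poor,
        flags=flags,
    )


def _zero_run_mask(activity: np.ndarray, min_run: int) -> np.ndarray:
    """Mask of epochs belonging to zero-count runs of length >= min_run."""
    if min_run <= 1:
        return activity == 0
    zero = activity == 0
    mask = np.zeros_like(zero)
    n = zero.size
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask
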