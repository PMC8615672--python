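"""Non-parametric circadian rhythm analysis: IS, IV, RA, L5 and M10.

The van Someren family of non-parametric rest-activity statistics, computed
on hourly-binned data by convention:

* interdaily stability (IS): variance of the average 24-h profile over the
  total variance, 0 (no day-to-day regularity) to 1 (identical days);
* intradaily variability (IV): normalized mean-square successive
  difference, near 0 for smooth rhythms and about 2 for uncorrelated data;
* L5 / M10: mean activity of the least-active 5-h and most-active 10-h
  windows of the average day, with their onsets;
* relative amplitude RA = (M10 - L5) / (M10 + L5).

Degenerate (zero-variance) inputs are flagged rather than given numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DayMatrix

__all__ = [
    "CircadianMetrics",
    "DegenerateSeriesError",
    "interdaily_stability",
    "intradaily_variability",
    "l5_m10",
    "relative_amplitude",
    "circadian_metrics",
]


class DegenerateSeriesError(ValueError):
    """Raised when a metric is undefined (zero variance, zero total activity)."""


def interdaily_stability(dm: DayMatrix) -> float:
    """IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2].

    ``p`` is bins per day, ``N = D * p`` total bins, ``xbar_h`` the mean
    over days of bin ``h`` and ``xbar`` the grand mean.  Requires at least
    two complete days and nonzero variance.
    """
    if dm.n_days < 2:
        raise ValueError("interdaily stability needs at least 2 complete days")
    x = dm.values
    p = dm.bins_per_day
    n = x.size
    xbar = x.mean()
    sst = ((x - xbar) ** 2).sum()
    if sst == 0:
        raise DegenerateSeriesError("zero-variance series: IS is 0/0")
    hourly_means = x.mean(axis=0)
    return float(n * ((hourly_means - xbar) ** 2).sum() / (p * sst))


def intradaily_variability(series: np.ndarray) -> float:
    """IV = [N * sum (x_i - x_{i-1})^2] / [(N-1) * sum (x_i - xbar)^2].

    Defined on the concatenated hourly series without resetting at day
    boundaries.  Values slightly above 2 are possible for anticorrelated
    series.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    n = x.size
    if n < 2:
        raise ValueError("intradaily variability needs at least 2 values")
    sst = ((x - x.mean()) ** 2).sum()
    if sst == 0:
        raise DegenerateSeriesError("zero-variance series: IV is 0/0")
    ssd = (np.diff(x) ** 2).sum()
    return float(n * ssd / ((n - 1) * sst))


def average_profile(dm: DayMatrix) -> np.ndarray:
    """The participant's average day: mean over days for each bin."""
    return dm.values.mean(axis=0)


def _window_means(profile: np.ndarray, width_bins: int) -> np.ndarray:
    """Mean over every wrap-around window of ``width_bins`` starting at each bin."""
    n = profile.size
    c = np.concatenate([profile, profile[: width_bins - 1]])
    cs = np.concatenate([[0.0], np.cumsum(c)])
    idx = np.arange(n)
    return (cs[idx + width_bins] - cs[idx]) / width_bins


def l5_m10(
    dm: DayMatrix,
    l_hours: float = 5.0,
    m_hours: float = 10.0,
    mode: str = "profile",
) -> tuple[float, float, float, float]:
    """Least-active 5-h and most-active 10-h window means with their onsets.

    Windows wrap around midnight; ties break to the earliest start.  In
    ``profile`` mode (the default) windows are searched on the average day;
    ``per_day`` searches each day separately and averages the results.

    Returns ``(L5, L5_onset_hours, M10, M10_onset_hours)``.
    """
    b = dm.bins_per_day
    lw = int(round(l_hours / dm.bin_hours))
    mw = int(round(m_hours / dm.bin_hours))
    if mode == "profile":
        profiles = [average_profile(dm)]
    elif mode == "per_day":
        profiles = list(dm.values)
    else:
        raise ValueError(f"unknown l5/m10 mode {mode!r}")
    l_vals, l_on, m_vals, m_on = [], [], [], []
    for prof in profiles:
        lm = _window_means(prof, lw)
        mm = _window_means(prof, mw)
        li = int(np.argmin(lm))
        mi = int(np.argmax(mm))
        l_vals.append(float(lm[li]))
        m_vals.append(float(mm[mi]))
        l_on.append((dm.day_start_clock_time + li * dm.bin_hours) % 24.0)
        m_on.append((dm.day_start_clock_time + mi * dm.bin_hours) % 24.0)
    from .phase import circular_mean_hours

    def _mean_time(times: list[float]) -> float:
        return times[0] if len(times) == 1 else circular_mean_hours(np.array(times))

    return (
        float(np.mean(l_vals)),
        _mean_time(l_on),
        float(np.mean(m_vals)),
        _mean_time(m_on),
    )


def relative_amplitude(l5: float, m10: float) -> float:
    """RA = (M10 - L5) / (M10 + L5); requires M10 + L5 > 0."""
    if l5 < 0 or m10 < l5:
        raise ValueError("need 0 <= L5 <= M10")
    if m10 + l5 == 0:
        raise DegenerateSeriesError("zero total activity: RA is 0/0")
    return float((m10 - l5) / (m10 + l5))


@dataclass
class CircadianMetrics:
    """Per-participant non-parametric rhythm metrics (plus spectral power)."""

    participant_id: str
    IS: float
    IV: float
    L5: float
    L5_onset: float
    M10: float
    M10_onset: float
    RA: float
    FFT_relpower: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "IS": self.IS,
            "IV": self.IV,
            "L5": self.L5,
            "L5_onset": self.L5_onset,
            "M10": self.M10,
            "M10_onset": self.M10_onset,
            "RA": self.RA,
            "FFT_relpower": self.FFT_relpower,
        }


def circadian_metrics(
    dm: DayMatrix, bin_hours: float = 1.0, l5m10_mode: str = "profile"
) -> CircadianMetrics:
    """Compute the full non-parametric metric set for one participant.

    The input matrix is rebinned to ``bin_hours`` (default hourly, the
    classical convention) before evaluation.
    """
    bins = int(round(24.0 / bin_hours))
    hourly = dm if dm.bins_per_day == bins else dm.rebin(bins)
    is_ = interdaily_stability(hourly)
    iv = intradaily_variability(hourly.flatten())
    l5, l5on, m10, m10on = l5_m10(hourly, mode=l5m10_mode)
    ra = relative_amplitude(l5, m10)
    return CircadianMetrics(dm.participant_id, is_, iv, l5, l5on, m10, m10on, ra)
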