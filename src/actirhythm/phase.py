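"""Rest-activity phase markers: template-matched onsets/offsets and cosinor fit.

Daily activity onset is the clock time at which a 5-h stretch of inactivity
gives way to a 5-h stretch of activity; the daily offset is the mirrored
transition.  Both are found by sliding a step template over the binarized
day and keeping the boundary with the highest match score.  Acrophase,
MESOR and amplitude come from an ordinary least-squares fit of a 24-h
cosine to each day's profile; per-participant phases are circular means so
that offsets near midnight do not wrap into artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DayMatrix

__all__ = [
    "PhaseEstimates",
    "template_match_onsets",
    "template_match_offsets",
    "cosinor_fit",
    "circular_mean_hours",
]


def circular_mean_hours(hours: np.ndarray) -> float:
    """Circular mean of clock times in hours, on [0, 24)."""
    h = np.asarray(hours, dtype=float)
    h = h[np.isfinite(h)]
    if h.size == 0:
        return float("nan")
    ang = h * 2 * np.pi / 24.0
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    out = float((mean * 24.0 / (2 * np.pi)) % 24.0)
    return 0.0 if out >= 24.0 else out


@dataclass
class PhaseEstimates:
    """Per-day and participant-level phase markers.

    All clock times are hours in [0, 24); undetectable days carry NaN.
    """

    participant_id: str
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    acrophases: np.ndarray = field(default_factory=lambda: np.array([]))
    mesors: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def onset(self) -> float:
        return circular_mean_hours(self.onsets)

    @property
    def offset(self) -> float:
        return circular_mean_hours(self.offsets)

    @property
    def acrophase(self) -> float:
        return circular_mean_hours(self.acrophases)

    @property
    def mesor(self) -> float:
        m = self.mesors[np.isfinite(self.mesors)]
        return float(m.mean()) if m.size else float("nan")

    @property
    def amplitude(self) -> float:
        a = self.amplitudes[np.isfinite(self.amplitudes)]
        return float(a.mean()) if a.size else float("nan")


def _binarize(dm: DayMatrix) -> np.ndarray:
    """A bin is active iff its count exceeds the participant's median bin count.

    Ties at the median count as active when the median coincides with the
    maximum (otherwise a majority-active day would binarize to all-low).
    """
    v = dm.values.reshape(-1)
    med = np.median(v)
    z = np.where(v > med, 1.0, -1.0)
    if med == v.max() and med > v.min():
        z[v == med] = 1.0
    return z


def _template_scores(z: np.ndarray, half_bins: int) -> np.ndarray:
    """Score every boundary position i of the concatenated +-1 series.

    score(i) = sum(z[i : i+half]) - sum(z[i-half : i]), with circular wrap
    over the full multi-day series; a maximal score marks a low->high step.
    """
    n = z.size
    c = np.concatenate([z, z])  # circular wrap
    cs = np.concatenate([[0.0], np.cumsum(c)])
    idx = np.arange(n)
    hi = cs[idx + half_bins] - cs[idx]
    lo_idx = (idx - half_bins) % n
    # low window may itself wrap; evaluate on the doubled series
    lo = cs[lo_idx + half_bins] - cs[lo_idx]
    return hi - lo


def _per_day_argmax(scores: np.ndarray, dm: DayMatrix) -> np.ndarray:
    b = dm.bins_per_day
    out = np.empty(dm.n_days)
    day_scores = scores.reshape(dm.n_days, b)
    flat_days = dm.values
    for d in range(dm.n_days):
        if np.ptp(flat_days[d]) == 0:  # constant day: no transition exists
            out[d] = np.nan
            continue
        j = int(np.argmax(day_scores[d]))  # earliest maximum wins (argmax is first)
        out[d] = (dm.day_start_clock_time + j * dm.bin_hours) % 24.0
    return out


def template_match_onsets(dm: DayMatrix, template_hours: float = 5.0) -> np.ndarray:
    """Per-day activity onset: boundary of 5 h low followed by 5 h high.

    Requires bins of at most 1 h.  Constant days yield NaN.
    """
    if dm.bin_hours > 1.0 + 1e-9:
        raise ValueError("template matching needs bins of 1 h or finer")
    half = int(round(template_hours / dm.bin_hours))
    scores = _template_scores(_binarize(dm), half)
    return _per_day_argmax(scores, dm)


def template_match_offsets(dm: DayMatrix, template_hours: float = 5.0) -> np.ndarray:
    """Per-day activity offset: boundary of 5 h high followed by 5 h low."""
    if dm.bin_hours > 1.0 + 1e-9:
        raise ValueError("template matching needs bins of 1 h or finer")
    half = int(round(template_hours / dm.bin_hours))
    scores = -_template_scores(_binarize(dm), half)
    return _per_day_argmax(scores, dm)


def cosinor_fit(dm: DayMatrix, period_hours: float = 24.0) -> PhaseEstimates:
    """Least-squares 24-h cosine fit per day: MESOR, amplitude, acrophase.

    Each day's profile is regressed on ``M + A cos(2 pi (t - phi)/P)`` via
    the linear sine/cosine parameterization; the acrophase is the clock
    time of the fitted peak.  Zero-variance days get amplitude 0 and an
    undefined (NaN) acrophase.
    """
    t = dm.bin_clock_hours()
    w = 2 * np.pi / period_hours
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    est = PhaseEstimates(dm.participant_id)
    mes, amp, acr = [], [], []
    for d in range(dm.n_days):
        y = dm.values[d]
        if np.ptp(y) == 0:
            mes.append(float(y[0]))
            amp.append(0.0)
            acr.append(np.nan)
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        m, bc, bs = beta
        a = float(np.hypot(bc, bs))
        phi = float(np.arctan2(bs, bc) / w % period_hours)  # peak time of fit
        mes.append(float(m))
        amp.append(a)
        acr.append(phi % 24.0)
    est.mesors = np.array(mes)
    est.amplitudes = np.array(amp)
    est.acrophases = np.array(acr)
    return est


def phase_estimates(dm: DayMatrix) -> PhaseEstimates:
    """Bundle template onsets/offsets and cosinor parameters for one participant."""
    est = cosinor_fit(dm)
    est.onsets = template_match_onsets(dm)
    est.offsets = template_match_offsets(dm)
    return est
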