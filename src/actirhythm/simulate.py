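"""Synthetic actigraphy cohorts with known ground truth.

Generates epoch-level activity, sleep diaries and cognitive outcomes for a
cohort structured like the study population: two diagnostic groups (DS,
TD) crossed with three age bands (children 6-10, adolescents 11-18, adults
19-26).  Each participant gets seven nights of 30-s epochs (recording noon
to noon, so six complete midnight-aligned days survive trimming).

The nightly timeline is: evening wind-down (low "quiet wake" activity)
from the activity-offset time, diary bedtime, a short latency, the sleep
span (near-zero counts plus Poisson-placed arousal bouts of elevated
activity), then the morning activity onset at the diary wake time.  A
shared per-night phase shift jitters the whole timeline, controlling
interdaily stability; daytime counts are gamma noise under a diurnal
envelope with a random-phase ultradian modulation, controlling intradaily
variability; arousal rate and bout size control WASO and L5.

Cognitive outcomes are linear in the participant's measured interdaily
stability and age with planted coefficients, so the inferential stage can
be exercised against known truth.

The six presets in :data:`STUDY_PRESETS` are calibrated so that pipeline
group means land near the target means in :data:`GROUP_TARGETS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DiaryNight, DiaryRecord, EpochSeries, trim_to_full_days, write_epoch_csv
from .npcra import circadian_metrics

__all__ = [
    "GroupParams",
    "GroundTruth",
    "CognitiveLink",
    "GROUP_TARGETS",
    "STUDY_PRESETS",
    "DEFAULT_BETAS",
    "generate_participant",
    "generate_cohort",
    "simulate_cohort_table",
]

EPOCH_SECONDS = 30
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS
BASE_DATE = pd.Timestamp("2021-03-01")  # a Monday; start weekday drawn per participant


@dataclass
class GroupParams:
    """Generator parameters for one group x age-band cell."""

    label: str
    group: str  # DS | TD
    age_group: str  # child | adolescent | adult
    n: int
    nights: int = 7
    # demographics
    age_mean: float = 10.0
    age_sd: float = 1.5
    age_range: tuple[float, float] = (6.0, 10.99)
    female_frac: float = 0.5
    # nightly timeline (clock hours; interval/latency in minutes)
    quiet_start: float = 20.5   # evening activity offset (wind-down begins)
    wake_time: float = 7.0      # morning activity onset = diary waketime
    interval_min: float = 560.0  # diary bed -> wake
    latency_min: float = 7.0    # bed -> biological sleep onset
    phase_jitter_sd: float = 0.3   # h, shared per-night shift
    bed_jitter_sd: float = 0.15    # h, independent bed+sleep shift
    wake_jitter_sd: float = 0.15   # h, independent wake shift
    # activity levels (counts per 30-s epoch)
    day_mean: float = 600.0
    day_shape: float = 1.2
    day_scale_sd: float = 0.15   # lognormal sd of per-day amplitude factor
    envelope_amp: float = 0.15   # diurnal modulation of daytime mean
    acrophase: float = 14.0      # envelope peak clock hour
    routine_amp: float = 0.8     # clock-locked within-day modulation (fixed phase)
    routine_period: float = 8.0  # h; must divide 24 for day-to-day repeatability
    ultradian_amp: float = 0.5   # random-phase-per-day within-day modulation
    ultradian_period: float = 6.0  # h
    burst_exp: float = 1.0       # burst sharpness (1 = half-wave, 2 = squared)
    quiet_mean: float = 60.0
    quiet_shape: float = 1.5
    night_base_mean: float = 4.0
    night_zero_prob: float = 0.7
    # nocturnal arousals
    arousal_rate: float = 8.0       # bouts / night
    arousal_bout_min: float = 8.0   # mean bout duration, minutes
    arousal_mean: float = 150.0     # counts/epoch during a bout

    def __post_init__(self) -> None:
        if self.nights < 5:
            raise ValueError("need at least 5 nights to pass inclusion QC")
        bed = (self.wake_time - self.interval_min / 60.0) % 24.0
        wind_down = (bed - self.quiet_start) % 24.0
        if wind_down > 6.0:
            raise ValueError(
                f"{self.label}: bedtime {bed:.2f} precedes quiet start {self.quiet_start:.2f}"
            )
        sleep_min = self.interval_min - self.latency_min
        if sleep_min <= 0:
            raise ValueError(f"{self.label}: non-positive sleep window")

    @property
    def bed_time(self) -> float:
        return (self.wake_time - self.interval_min / 60.0) % 24.0

    @property
    def sleep_time(self) -> float:
        return (self.bed_time + self.latency_min / 60.0) % 24.0


@dataclass
class CognitiveLink:
    """Planted linear link: outcome = b0 + b_is * IS + b_age * age + N(0, sd)."""

    intercept: float
    beta_is: float
    beta_age: float
    sd: float


#: Sign structure: stronger day-to-day stability slows reaction time and
#: lowers verbal/scene recall; other outcomes carry no planted rhythm effect.
DEFAULT_BETAS: dict[str, CognitiveLink] = {
    "reaction_time": CognitiveLink(1.0, 3.0, 0.03, 0.45),
    "verbal_recall": CognitiveLink(30.0, -14.0, 0.1, 4.0),
    "scene_recall": CognitiveLink(12.0, -5.0, 0.05, 1.6),
    "visual_recall": CognitiveLink(8.0, 0.0, 0.05, 1.8),
    "spatial_recall": CognitiveLink(10.0, 0.0, 0.15, 3.5),
    "object_binding": CognitiveLink(8.0, 0.0, 0.25, 3.0),
    "kbit_verbal": CognitiveLink(40.0, 0.0, 0.5, 9.0),
    "brief_gec": CognitiveLink(60.0, 0.0, 0.0, 8.0),
}


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed: int
    betas: dict[str, CognitiveLink] = field(default_factory=dict)
    participants: dict[str, dict] = field(default_factory=dict)


def _night_segments(p: GroupParams, rng: np.random.Generator, nights: int):
    """Absolute hours (from recording start midnight) of each night's
    quiet-start, bed, sleep-onset and wake times."""
    wind_down = (p.bed_time - p.quiet_start) % 24.0
    segs = []
    for n in range(nights):
        delta = rng.normal(0.0, p.phase_jitter_sd)
        eb = rng.normal(0.0, p.bed_jitter_sd)
        ew = rng.normal(0.0, p.wake_jitter_sd)
        w = 24.0 * (n + 1) + p.wake_time + delta + ew
        b = w - p.interval_min / 60.0 + eb - ew
        s = b + p.latency_min / 60.0
        q = b - wind_down
        if w <= s + 1.0:  # degenerate jitter draw: keep ordering sane
            w = s + 1.0
        segs.append((q, b, s, w))
    return segs


def generate_participant(
    params: GroupParams, seed, participant_id: str | None = None
) -> tuple[EpochSeries, DiaryRecord, dict]:
    """Generate one participant's epoch series, diary and ground-truth slice.

    Deterministic given (params, seed).  The recording runs from noon of
    day 0 to noon of day ``nights``, so all ``nights`` nights are fully
    observed and ``nights - 1`` complete midnight-aligned days remain
    after trimming.
    """
    rng = np.random.default_rng(seed)
    pid = participant_id or f"{params.label}_{int(rng.integers(1e6)):06d}"
    start_offset_days = int(rng.integers(0, 7))
    start = BASE_DATE + pd.Timedelta(days=start_offset_days, hours=12)
    total_hours = params.nights * 24.0
    n_epochs = int(total_hours * EPOCHS_PER_HOUR)
    # absolute hour (from the midnight before `start`) of each epoch start
    t = 12.0 + np.arange(n_epochs) / EPOCHS_PER_HOUR

    segs = _night_segments(params, rng, params.nights)
    state = np.zeros(n_epochs, dtype=np.int8)  # 0 day, 1 quiet wake, 2 sleep
    for q, b, s, w in segs:
        state[(t >= q) & (t < s)] = 1
        state[(t >= s) & (t < w)] = 2

    activity = np.zeros(n_epochs)
    day_idx = np.floor(t / 24.0).astype(int)
    day_factor = np.exp(rng.normal(0.0, params.day_scale_sd, params.nights + 1))
    routine_phase = rng.uniform(0, 2 * np.pi)  # fixed per participant: a daily routine
    ultra_phase = rng.uniform(0, 2 * np.pi, params.nights + 1)
    clock = t % 24.0
    env = 1.0 + params.envelope_amp * np.cos(2 * np.pi * (clock - params.acrophase) / 24.0)
    # activity bursts (squared half-wave rectified sinusoids): activity rises
    # above the daytime baseline in episodes but never dips below it, so
    # rest-activity transitions stay sharp while ultradian-band power grows
    routine = np.maximum(np.sin(2 * np.pi * clock / params.routine_period + routine_phase),
                         0.0) ** params.burst_exp
    ultra = np.maximum(np.sin(2 * np.pi * t / params.ultradian_period + ultra_phase[day_idx]),
                       0.0) ** params.burst_exp
    burst = 1.0 + params.routine_amp * routine + params.ultradian_amp * ultra
    burst /= burst.mean()
    mean_day = (
        params.day_mean * day_factor[day_idx] * np.clip(env, 0.05, None) * burst
    )
    m = state == 0
    if np.isfinite(params.day_shape):
        activity[m] = rng.gamma(params.day_shape, mean_day[m] / params.day_shape)
    else:  # infinite shape: zero-variance (deterministic) daytime counts
        activity[m] = mean_day[m]
    m = state == 1
    if np.isfinite(params.quiet_shape):
        activity[m] = rng.gamma(params.quiet_shape, params.quiet_mean / params.quiet_shape,
                                m.sum())
    else:
        activity[m] = params.quiet_mean
    m = state == 2
    base_night = rng.gamma(1.0, params.night_base_mean, m.sum())
    base_night[rng.random(m.sum()) < params.night_zero_prob] = 0.0
    activity[m] = base_night

    # nocturnal arousal bouts
    arousal_minutes = []
    arousal_mask = np.zeros(n_epochs, bool)
    for q, b, s, w in segs:
        n_bouts = rng.poisson(params.arousal_rate)
        minutes = 0.0
        for _ in range(n_bouts):
            dur_min = max(1.0, rng.gamma(2.0, params.arousal_bout_min / 2.0))
            t0 = rng.uniform(s + 10 / 60, max(s + 10 / 60, w - 10 / 60 - dur_min / 60))
            i0 = int(np.searchsorted(t, t0))
            i1 = min(n_epochs, i0 + int(round(dur_min * 2)))
            arousal_mask[i0:i1] = True
            minutes += (i1 - i0) / 2.0
        arousal_minutes.append(minutes)
    k = arousal_mask.sum()
    if k:
        activity[arousal_mask] = rng.gamma(1.0, params.arousal_mean, k)

    series = EpochSeries(
        participant_id=pid,
        start=start,
        epoch_length=EPOCH_SECONDS,
        activity=np.round(activity),
    )
    midnight0 = start.normalize()
    nights = [
        DiaryNight(
            date=midnight0 + pd.Timedelta(days=int(b // 24)),
            bedtime=midnight0 + pd.Timedelta(hours=b),
            waketime=midnight0 + pd.Timedelta(hours=w),
        )
        for q, b, s, w in segs
    ]
    diary = DiaryRecord(pid, nights)
    truth = {
        "participant_id": pid,
        "segments": [tuple(map(float, s)) for s in segs],
        "arousal_minutes": arousal_minutes,
        "true_waso_scored_target": float(np.mean(arousal_minutes)),
        "start": str(start),
    }
    return series, diary, truth


# ---------------------------------------------------------------------------
# calibrated presets

#: Target group means the presets are calibrated against (used by tests and
#: for reporting; units: minutes, percent, clock hours, counts/epoch).
GROUP_TARGETS: dict[str, dict[str, float]] = {
    "children_DS": dict(TST=469.37, SE=83.85, WASO=83.18, onset=6.69, offset=20.76,
                        IS=0.80, IV=0.53, L5=22.53, M10=614.73, FFT=0.31, acrophase=13.62),
    "children_TD": dict(TST=482.40, SE=89.32, WASO=53.23, onset=7.014, offset=20.48,
                        IS=0.71, IV=0.64, L5=13.76, M10=687.0, FFT=0.27, acrophase=13.59),
    "adolescents_DS": dict(TST=438.32, SE=85.98, WASO=64.74, onset=6.59, offset=20.92,
                           IS=0.71, IV=0.72, L5=17.64, M10=403.75, FFT=0.22, acrophase=14.16),
    "adolescents_TD": dict(TST=439.61, SE=89.63, WASO=46.86, onset=7.57, offset=22.23,
                           IS=0.58, IV=0.85, L5=14.94, M10=376.74, FFT=0.14, acrophase=14.88),
    "adults_DS": dict(TST=398.61, SE=83.73, WASO=69.11, onset=7.19, offset=21.83,
                      IS=0.60, IV=0.81, L5=23.00, M10=363.89, FFT=0.23, acrophase=14.30),
    "adults_TD": dict(TST=376.12, SE=87.36, WASO=41.27, onset=7.80, offset=22.40,
                      IS=0.59, IV=0.77, L5=18.53, M10=376.69, FFT=0.15, acrophase=15.82),
}

#: Printed group SDs for the same measures (for standard-error tolerances).
GROUP_TARGET_SDS: dict[str, dict[str, float]] = {
    "children_DS": dict(TST=51.59, SE=5.05, WASO=24.93, onset=0.60, offset=0.77,
                        IS=0.09, IV=0.141, L5=10.93, M10=171.56, FFT=0.07),
    "children_TD": dict(TST=40.43, SE=2.68, WASO=13.01, onset=1.140, offset=0.96,
                        IS=0.08, IV=0.14, L5=5.02, M10=107.28, FFT=0.06),
    "adolescents_DS": dict(TST=53.40, SE=3.37, WASO=16.80, onset=1.08, offset=1.21,
                           IS=0.09, IV=0.19, L5=6.08, M10=110.36, FFT=0.06),
    "adolescents_TD": dict(TST=66.73, SE=2.62, WASO=18.91, onset=1.21, offset=1.59,
                           IS=0.17, IV=0.22, L5=14.89, M10=138.78, FFT=0.06),
    "adults_DS": dict(TST=55.83, SE=6.67, WASO=34.71, onset=1.24, offset=1.47,
                      IS=0.14, IV=0.26, L5=15.30, M10=122.82, FFT=0.17),
    "adults_TD": dict(TST=51.49, SE=3.52, WASO=10.96, onset=2.97, offset=3.53,
                      IS=0.11, IV=0.22, L5=10.72, M10=62.81, FFT=0.040),
}

_GROUP_NS = {"children_DS": 20, "children_TD": 20, "adolescents_DS": 28,
             "adolescents_TD": 13, "adults_DS": 10, "adults_TD": 10}

_DEMOGRAPHICS = {
    "children_DS": dict(age_mean=7.95, age_sd=1.16, age_range=(6.0, 10.99), female_frac=8 / 20),
    "children_TD": dict(age_mean=7.53, age_sd=1.15, age_range=(6.0, 10.99), female_frac=10 / 20),
    "adolescents_DS": dict(age_mean=15.11, age_sd=2.21, age_range=(11.0, 18.99), female_frac=16 / 28),
    "adolescents_TD": dict(age_mean=14.84, age_sd=2.12, age_range=(11.0, 18.99), female_frac=5 / 13),
    "adults_DS": dict(age_mean=22.76, age_sd=2.02, age_range=(19.0, 26.99), female_frac=3 / 10),
    "adults_TD": dict(age_mean=21.94, age_sd=1.17, age_range=(19.0, 26.99), female_frac=6 / 10),
}

# Per-group generator knobs calibrated against GROUP_TARGETS.  wake_shift /
# quiet_shift place the simulated schedule so that the template-matched
# markers (which sit a few bins inside the activity shoulders) land on the
# target clock times.
_CALIBRATION = {
    'children_DS': dict(phase_jitter_sd=0.26, day_mean=490.0, day_scale_sd=0.2, routine_amp=6.0, ultradian_amp=3.4, envelope_amp=0.1, arousal_rate=7.8, arousal_bout_min=9.0, arousal_mean=175.0, night_base_mean=6.0, night_zero_prob=0.6, wake_shift=-0.2, quiet_shift=0.4, acro_shift=-0.27),
    'children_TD': dict(phase_jitter_sd=0.85, day_mean=590.0, day_scale_sd=0.22, routine_amp=9.0, ultradian_amp=6.5, envelope_amp=0.1, arousal_rate=5.3, arousal_bout_min=8.5, arousal_mean=150.0, night_base_mean=5.0, night_zero_prob=0.6, wake_shift=-0.14, quiet_shift=0.36, acro_shift=-0.34),
    'adolescents_DS': dict(phase_jitter_sd=0.65, day_mean=345.0, day_scale_sd=0.25, routine_amp=10.0, ultradian_amp=6.5, envelope_amp=0.1, arousal_rate=7.0, arousal_bout_min=8.5, arousal_mean=145.0, night_base_mean=5.0, night_zero_prob=0.6, wake_shift=-0.41, quiet_shift=0.73, acro_shift=0.08),
    'adolescents_TD': dict(phase_jitter_sd=1.2, day_mean=320.0, day_scale_sd=0.3, routine_amp=13.0, ultradian_amp=8.0, envelope_amp=0.1, ultradian_period=5.0, arousal_rate=5.2, arousal_bout_min=8.0, arousal_mean=150.0, night_base_mean=4.0, night_zero_prob=0.6, wake_shift=-0.23, quiet_shift=0.57, acro_shift=-0.4),
    'adults_DS': dict(phase_jitter_sd=0.95, day_mean=310.0, day_scale_sd=0.25, routine_amp=8.5, ultradian_amp=7.0, envelope_amp=0.1, ultradian_period=5.0, arousal_rate=7.4, arousal_bout_min=8.5, arousal_mean=155.0, night_base_mean=5.0, night_zero_prob=0.6, wake_shift=-0.2, quiet_shift=0.6, acro_shift=-0.32),
    'adults_TD': dict(phase_jitter_sd=1.45, day_mean=300.0, day_scale_sd=0.3, routine_amp=14.0, ultradian_amp=9.5, envelope_amp=0.1, ultradian_period=5.0, arousal_rate=4.3, arousal_bout_min=8.0, arousal_mean=150.0, night_base_mean=5.0, night_zero_prob=0.6, wake_shift=-0.44, quiet_shift=0.7, acro_shift=0.26),
}


def _make_preset(label: str) -> GroupParams:
    tgt = GROUP_TARGETS[label]
    knobs = dict(_CALIBRATION[label])
    wake_shift = knobs.pop("wake_shift", 0.0)
    quiet_shift = knobs.pop("quiet_shift", 0.0)
    acro_shift = knobs.pop("acro_shift", 0.0)
    group = "DS" if label.endswith("DS") else "TD"
    age_group = {"chi": "child", "ado": "adolescent", "adu": "adult"}[label[:3]]
    interval = tgt["TST"] / tgt["SE"] * 100.0
    latency = interval - (tgt["TST"] + tgt["WASO"])
    wake = tgt["onset"] + wake_shift
    bed = (wake - interval / 60.0) % 24.0
    quiet = (tgt["offset"] + quiet_shift) % 24.0
    if (bed - quiet) % 24.0 > 6.0:  # quiet start may not precede bed by > 6 h
        quiet = (bed - 0.05) % 24.0
    return GroupParams(
        label=label,
        group=group,
        age_group=age_group,
        n=_GROUP_NS[label],
        quiet_start=quiet,
        wake_time=wake,
        interval_min=interval,
        latency_min=max(2.0, latency),
        acrophase=tgt["acrophase"] + acro_shift,
        **_DEMOGRAPHICS[label],
        **knobs,
    )


STUDY_PRESETS: dict[str, GroupParams] = {k: _make_preset(k) for k in GROUP_TARGETS}


# ---------------------------------------------------------------------------
# cohort generation


def _measured_is(series: EpochSeries) -> float:
    dm = trim_to_full_days(series, bins_per_day=24)
    return circadian_metrics(dm).IS


def generate_cohort(
    groups: list[GroupParams] | None = None,
    betas: dict[str, CognitiveLink] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[EpochSeries, DiaryRecord]], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: participants, cohort table and ground truth.

    Cognitive outcomes are generated for DS participants only (mirroring
    the study design, where cognitive testing covered the DS groups) from
    the planted linear links in ``betas`` applied to each participant's
    measured interdaily stability and age.  When ``out_dir`` is given, the
    same CSV dialects the io module reads are written there.
    """
    groups = list(STUDY_PRESETS.values()) if groups is None else groups
    betas = DEFAULT_BETAS if betas is None else betas
    truth = GroundTruth(seed=seed, betas=dict(betas))
    participants: list[tuple[EpochSeries, DiaryRecord]] = []
    rows = []
    root = np.random.SeedSequence(seed)
    for gi, g in enumerate(groups):
        for i in range(g.n):
            child_seed = np.random.SeedSequence(entropy=seed, spawn_key=(gi, i))
            s_act, s_demo = child_seed.spawn(2)
            rng = np.random.default_rng(s_demo)
            pid = f"{g.label}_{i:02d}"
            series, diary, slice_ = generate_participant(g, s_act, participant_id=pid)
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), *g.age_range))
            gender = "F" if rng.random() < g.female_frac else "M"
            # weekend days among the complete midnight-aligned days
            dm = trim_to_full_days(series)
            dates = pd.date_range(dm.first_day_date, periods=dm.n_days)
            weekend = int(np.sum(dates.dayofweek >= 5))
            is_hat = _measured_is(series)
            row = {
                "participant_id": pid,
                "group": g.group,
                "age_group": g.age_group,
                "age": age,
                "gender": gender,
                "weekend_days": weekend,
            }
            if g.group == "DS":
                for name, link in betas.items():
                    row[name] = (
                        link.intercept + link.beta_is * is_hat + link.beta_age * age
                        + rng.normal(0.0, link.sd)
                    )
                row["ef_accuracy"] = float(np.clip(rng.normal(0.88, 0.07), 0.4, 1.0))
            slice_.update(age=age, gender=gender, measured_is=is_hat)
            truth.participants[pid] = slice_
            participants.append((series, diary))
            rows.append(row)
    cohort = pd.DataFrame(rows)
    if out_dir is not None:
        _write_cohort(out_dir, participants, cohort, truth)
    return participants, cohort, truth


def _write_cohort(out_dir, participants, cohort: pd.DataFrame, truth: GroundTruth) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diary_rows = []
    for series, diary in participants:
        write_epoch_csv(series, out / f"{series.participant_id}.csv")
        for night in diary.nights:
            diary_rows.append(
                {
                    "participant_id": diary.participant_id,
                    "date": night.date.date(),
                    "bedtime": night.bedtime.strftime("%H:%M:%S"),
                    "waketime": night.waketime.strftime("%H:%M:%S"),
                    "n_wakings": night.n_wakings,
                    "nap_intervals": "",
                }
            )
    pd.DataFrame(diary_rows).to_csv(out / "diary.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    payload = {
        "seed": truth.seed,
        "betas": {k: vars(v) for k, v in truth.betas.items()},
        "participants": truth.participants,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=1, default=str))


def simulate_cohort_table(
    n: int,
    betas: dict[str, CognitiveLink] | None = None,
    seed: int = 0,
    groups: tuple[str, ...] = ("DS", "TD"),
    age_groups: tuple[str, ...] = ("child", "adolescent", "adult"),
) -> pd.DataFrame:
    """Fast cohort-table-only simulation (no actigraphy) for the stats stage.

    Draws plausible rhythm/sleep covariates directly and applies the
    planted cognitive links; useful for calibration and power studies of
    the inferential protocol where epoch-level data are irrelevant.
    """
    rng = np.random.default_rng(seed)
    betas = DEFAULT_BETAS if betas is None else betas
    age_lims = {"child": (6, 11), "adolescent": (11, 19), "adult": (19, 27)}
    rows = []
    for i in range(n):
        grp = groups[i % len(groups)]
        ag = age_groups[(i // len(groups)) % len(age_groups)]
        age = rng.uniform(*age_lims[ag])
        is_ = float(np.clip(rng.normal(0.68, 0.12), 0.2, 0.98))
        se = float(np.clip(rng.normal(86.0, 4.0), 60, 99))
        row = {
            "participant_id": f"sim_{i:03d}",
            "group": grp,
            "age_group": ag,
            "age": age,
            "gender": "F" if rng.random() < 0.5 else "M",
            "weekend_days": int(rng.integers(1, 3)),
            "IS": is_,
            "SE": se,
        }
        for name, link in betas.items():
            row[name] = link.intercept + link.beta_is * is_ + link.beta_age * age + rng.normal(
                0.0, link.sd
            )
        rows.append(row)
    return pd.DataFrame(rows)
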