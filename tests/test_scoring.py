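import numpy as np
import pandas as pd
import pytest

from actirhythm.io import DiaryNight, DiaryRecord, EpochSeries, trim_to_full_days
from actirhythm.phase import template_match_offsets, template_match_onsets
from actirhythm.scoring import (
    DEFAULT_KERNEL_30S,
    RestInterval,
    resolve_rest_intervals,
    score_epochs,
    summarize_sleep,
)
from actirhythm.simulate import STUDY_PRESETS, generate_participant


def _series(activity, start="2021-03-01 00:00:00"):
    return EpochSeries("p", start, 30, np.asarray(activity, dtype=float))


class TestScoreEpochs:
    def test_all_zero_activity_scores_sleep(self):
        assert not score_epochs(_series(np.zeros(100))).any()

    def test_constant_high_activity_scores_wake(self):
        assert score_epochs(_series(np.full(100, 1000.0))).all()

    def test_single_spike_matches_hand_convolution(self):
        act = np.zeros(41)
        act[20] = 10_000
        labels = score_epochs(_series(act))
        # independent oracle: weighted sum computed epoch by epoch
        for i in range(41):
            total = 0.0
            for k, w in enumerate(DEFAULT_KERNEL_30S):
                j = i + k - 4
                if 0 <= j < 41:
                    total += w * act[j]
            assert labels[i] == (total > 40.0), i
        assert labels[20]
        assert labels[16] and labels[24]  # 1/25 * 10000 = 400 > 40
        assert not labels[15] and not labels[25]

    def test_kernel_longer_than_series_raises(self):
        with pytest.raises(ValueError, match="kernel"):
            score_epochs(_series(np.zeros(5)))

    def test_tst_monotone_in_threshold(self):
        series, diary, _ = generate_participant(STUDY_PRESETS["children_DS"], 11, "m")
        intervals = resolve_rest_intervals(series, diary)
        last = -1.0
        for thr in (10.0, 40.0, 160.0, 640.0):
            labels = score_epochs(series, threshold=thr)
            tst = summarize_sleep(series, labels, intervals).tst
            assert tst >= last
            last = tst


class TestRestIntervals:
    def test_diary_passthrough(self):
        s = _series(np.zeros(2 * 2880))
        diary = DiaryRecord("p", [DiaryNight("2021-03-01", "2021-03-01 21:00",
                                             "2021-03-02 06:30")])
        (iv,) = resolve_rest_intervals(s, diary)
        assert iv.start == pd.Timestamp("2021-03-01 21:00")
        assert iv.duration_minutes == 570.0

    def test_midnight_wrap(self):
        night = DiaryNight("2021-03-01", "2021-03-01 21:00", "2021-03-01 06:30")
        assert (night.waketime - night.bedtime) == pd.Timedelta(hours=9.5)

    def test_auto_intervals_from_markers(self, square_wave_series):
        dm = trim_to_full_days(square_wave_series, bins_per_day=96)
        onsets = template_match_onsets(dm)
        offsets = template_match_offsets(dm)
        ivs = resolve_rest_intervals(square_wave_series, None,
                                     auto_markers=(offsets, onsets))
        assert len(ivs) == 5
        for iv in ivs:
            # true rest span is 21:00 -> 07:00; one 15-min bin of slack
            assert abs(iv.start.hour + iv.start.minute / 60 - 21.0) <= 0.25
            assert abs(iv.end.hour + iv.end.minute / 60 - 7.0) <= 0.25


class TestSummarizeSleep:
    def _interval(self, minutes=480.0):
        return [RestInterval(0, "2021-03-01 22:00",
                             pd.Timestamp("2021-03-01 22:00") + pd.Timedelta(minutes=minutes))]

    def test_perfect_night(self):
        s = _series(np.zeros(2880), start="2021-03-01 12:00:00")
        labels = np.zeros(2880, bool)
        summ = summarize_sleep(s, labels, self._interval())
        (n,) = summ.nights
        assert (n.tst_minutes, n.waso_minutes, n.efficiency) == (480.0, 0.0, 100.0)

    def test_scattered_wake_after_onset(self):
        s = _series(np.zeros(2880), start="2021-03-01 12:00:00")
        labels = np.zeros(2880, bool)
        i0 = 10 * 120  # 22:00 is 10 h after the noon start
        rng = np.random.default_rng(0)
        # 60 scattered wake minutes strictly after the first 10 sleep minutes
        wake_min = rng.choice(np.arange(15, 480), size=60, replace=False)
        for m in wake_min:
            labels[i0 + 2 * m : i0 + 2 * m + 2] = True
        (n,) = summarize_sleep(s, labels, self._interval()).nights
        assert n.tst_minutes == 420.0
        assert n.waso_minutes == 60.0
        assert n.efficiency == pytest.approx(87.5)

    def test_identity_latency_tst_waso(self):
        series, diary, _ = generate_participant(STUDY_PRESETS["adults_DS"], 5, "x")
        labels = score_epochs(series)
        summ = summarize_sleep(series, labels, resolve_rest_intervals(series, diary))
        for n in summ.valid_nights:
            assert n.latency_minutes + n.tst_minutes + n.waso_minutes == pytest.approx(
                n.interval_minutes, abs=1e-9)

    def test_no_sleep_onset_flagged(self):
        s = _series(np.full(2880, 1000.0), start="2021-03-01 12:00:00")
        labels = np.ones(2880, bool)
        summ = summarize_sleep(s, labels, self._interval())
        assert not summ.nights[0].valid
        assert summ.nights[0].flag == "no_sleep_onset"

    def test_waso_tracks_simulated_arousal_truth(self):
        # scored WASO follows the generator's arousal-minute ground truth,
        # allowing for kernel smear at bout edges
        diffs = []
        for seed in range(8):
            series, diary, truth = generate_participant(
                STUDY_PRESETS["children_DS"], seed + 100, "w")
            labels = score_epochs(series)
            summ = summarize_sleep(series, labels, resolve_rest_intervals(series, diary))
            diffs.append(summ.waso - np.mean(truth["arousal_minutes"]))
        assert 0 <= np.mean(diffs) <= 25.0
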