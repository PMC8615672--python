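import numpy as np
import pytest
from dataclasses import replace

from actirhythm.io import DayMatrix, trim_to_full_days
from actirhythm.npcra import (
    DegenerateSeriesError,
    circadian_metrics,
    interdaily_stability,
    intradaily_variability,
    l5_m10,
    relative_amplitude,
)
from actirhythm.simulate import STUDY_PRESETS, generate_participant


def _iv_oracle(x):
    """Direct loop evaluation of the normalized mean-square successive difference."""
    x = np.asarray(x, float)
    n = len(x)
    num = sum((x[i] - x[i - 1]) ** 2 for i in range(1, n)) * n
    den = sum((v - x.mean()) ** 2 for v in x) * (n - 1)
    return num / den


def _is_oracle(values):
    """Direct loop evaluation of the interdaily stability formula."""
    d, p = values.shape
    n = d * p
    xbar = values.mean()
    hourly = values.mean(axis=0)
    return n * sum((h - xbar) ** 2 for h in hourly) / (p * ((values - xbar) ** 2).sum())


class TestInterdailyStability:
    def test_identical_days_reach_upper_bound(self):
        rng = np.random.default_rng(1)
        prof = rng.gamma(1, 100, 24)
        dm = DayMatrix("t", np.tile(prof, (6, 1)))
        assert interdaily_stability(dm) == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_toy_matrix(self):
        vals = np.array([[0, 0, 10, 10], [10, 10, 0, 0]], dtype=float)
        dm = DayMatrix("t", vals)
        assert interdaily_stability(dm) == pytest.approx(_is_oracle(vals))
        assert interdaily_stability(dm) == pytest.approx(0.0, abs=1e-12)

    def test_iid_noise_expectation_one_over_days(self):
        # under exchangeability the expected stability is ~ 1/D
        vals = [
            interdaily_stability(DayMatrix(
                "t", np.random.default_rng(s).gamma(1, 10, (6, 24))))
            for s in range(80)
        ]
        assert np.mean(vals) == pytest.approx(1 / 6, abs=0.03)

    def test_needs_two_days_and_variance(self):
        with pytest.raises(ValueError, match="2 complete days"):
            interdaily_stability(DayMatrix("t", np.ones((1, 24))))
        with pytest.raises(DegenerateSeriesError):
            interdaily_stability(DayMatrix("t", np.ones((3, 24))))

    def test_decreases_with_day_to_day_phase_jitter(self):
        base = replace(STUDY_PRESETS["children_DS"], arousal_rate=0.0)
        means = []
        for jitter in (0.1, 0.8, 2.0):
            p = replace(base, phase_jitter_sd=jitter)
            vals = []
            for s in range(20):
                series, _, _ = generate_participant(p, 1000 + s, "j")
                dm = trim_to_full_days(series, bins_per_day=24)
                vals.append(interdaily_stability(dm))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestIntradailyVariability:
    def test_slow_sinusoid_is_smooth(self):
        t = np.arange(144)
        x = 100 + 50 * np.sin(2 * np.pi * t / 24)
        assert intradaily_variability(x) == pytest.approx(_iv_oracle(x))
        assert intradaily_variability(x) < 0.2

    def test_strict_alternation_is_maximal(self):
        x = np.tile([0.0, 10.0], 72)
        iv = intradaily_variability(x)
        assert iv == pytest.approx(_iv_oracle(x))
        assert iv > 2.0  # anticorrelated series exceed the nominal range

    def test_matches_oracle_on_random_data(self):
        x = np.random.default_rng(7).gamma(1, 10, 144)
        assert intradaily_variability(x) == pytest.approx(_iv_oracle(x), rel=1e-12)

    def test_degenerate_flagged(self):
        with pytest.raises(DegenerateSeriesError):
            intradaily_variability(np.full(50, 3.0))

    def test_increases_with_arousal_rate(self):
        base = STUDY_PRESETS["children_DS"]
        means = []
        for rate in (0.0, 8.0, 25.0):
            p = replace(base, arousal_rate=rate)
            vals = []
            for s in range(20):
                series, _, _ = generate_participant(p, 2000 + s, "a")
                dm = trim_to_full_days(series, bins_per_day=24)
                vals.append(intradaily_variability(dm.flatten()))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAffineInvariance:
    @pytest.mark.parametrize("a,b", [(2.5, 0.0), (0.3, 40.0), (-1.0, 100.0)])
    def test_is_and_iv_invariant(self, a, b):
        rng = np.random.default_rng(9)
        vals = rng.gamma(2, 20, (6, 24))
        dm = DayMatrix("t", vals)
        dm_t = DayMatrix("t", np.clip(a * vals + b, 0, None)) if a > 0 else None
        transformed = a * vals + b
        # DayMatrix requires non-negative cells; evaluate the formulas directly
        assert interdaily_stability(dm) == pytest.approx(
            _is_oracle(transformed), rel=1e-9)
        assert intradaily_variability(vals.reshape(-1)) == pytest.approx(
            _iv_oracle(transformed.reshape(-1)), rel=1e-9)


class TestL5M10:
    def test_square_wave_windows(self):
        h = np.arange(24)
        prof = np.where((h >= 7) & (h < 21), 600.0, 0.0)
        l5, l5on, m10, m10on = l5_m10(DayMatrix("t", prof[None, :]))
        assert (l5, m10) == (0.0, 600.0)

    def test_single_active_hour_bruteforce(self):
        prof = np.zeros(24)
        prof[13] = 240.0
        l5, _, m10, m10on = l5_m10(DayMatrix("t", prof[None, :]))
        # exhaustive oracle over all 24 wrap-around windows
        best = max(np.mean([prof[(s + j) % 24] for j in range(10)]) for s in range(24))
        assert m10 == pytest.approx(best) == pytest.approx(24.0)
        assert l5 == 0.0

    def test_sliding_equals_bruteforce_always(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            prof = rng.gamma(1, 50, 24)
            l5, l5on, m10, m10on = l5_m10(DayMatrix("t", prof[None, :]))
            wins5 = [np.mean([prof[(s + j) % 24] for j in range(5)]) for s in range(24)]
            wins10 = [np.mean([prof[(s + j) % 24] for j in range(10)]) for s in range(24)]
            assert l5 == pytest.approx(min(wins5), rel=1e-12)
            assert m10 == pytest.approx(max(wins10), rel=1e-12)
            assert l5on == float(np.argmin(wins5))
            assert m10on == float(np.argmax(wins10))


class TestRelativeAmplitude:
    def test_boundary_values(self):
        assert relative_amplitude(0.0, 100.0) == 1.0
        assert relative_amplitude(50.0, 50.0) == 0.0

    def test_printed_group_means_arithmetic(self):
        # L5 and M10 group means of healthy children imply RA ~ 0.9607
        assert relative_amplitude(13.76, 687.0) == pytest.approx(0.9607, abs=5e-5)

    def test_zero_total_flagged(self):
        with pytest.raises(DegenerateSeriesError):
            relative_amplitude(0.0, 0.0)


def test_full_metric_bundle(square_wave_series):
    dm = trim_to_full_days(square_wave_series)
    met = circadian_metrics(dm)
    assert met.IS == pytest.approx(1.0)
    assert met.RA == 1.0
    assert met.L5 == 0.0 and met.M10 == 600.0
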