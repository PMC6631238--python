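"""Restriction layer: meal-probability gating, minute rules, D1, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipbite.core import Window
from sipbite.postprocessing import (
    MealProbabilityProfile,
    apply_D1,
    apply_E1,
    apply_E2,
    apply_E3,
    energy_signal,
    fuse,
    meal_evidence,
    meal_probability,
    minute_smooth,
    windows_to_units,
)


class TestMealProbability:
    def test_lunch_center_clips_to_one(self):
        assert meal_probability(12.5) == pytest.approx(1.0)

    def test_night_probability_tiny(self):
        p = meal_probability(3.0)
        assert p == pytest.approx(0.004, abs=0.002)
        assert p < 0.5

    def test_symmetry_about_lunch(self):
        # 11:00 and 14:00 share the lunch component; they differ exactly by
        # the breakfast and dinner tails (closed form)
        def tails(t):
            return sum(np.exp(-((t - c) ** 2) / 4.5) for c in (8.0, 20.0))

        diff = meal_probability(11.0) - meal_probability(14.0)
        assert diff == pytest.approx(tails(11.0) - tails(14.0), abs=1e-12)

    def test_bounded_and_max_attained_at_centers(self):
        t = np.linspace(0, 24, 2401)
        p = MealProbabilityProfile()(t)
        assert np.all((0 <= p) & (p <= 1))
        for c in (8.0, 12.5, 20.0):
            assert meal_probability(c) == pytest.approx(p.max())


class TestE1:
    def test_all_ones_eating(self):
        ones = np.ones(10)
        flags = apply_E1(ones, ones, N=3)
        assert flags[3:].all()
        # literal formula: N+1 unit terms over N
        assert meal_evidence(ones, ones, N=3)[5] == pytest.approx(4 / 3)

    def test_all_zeros_not_eating(self):
        z = np.zeros(10)
        assert not apply_E1(z, z, N=3).any()

    def test_boundary_exactly_half_not_eating(self):
        pclass = np.array([0.6, 0.7, 0.8, 0.9])
        ptime = np.full(4, 0.5)
        assert meal_evidence(pclass, ptime, N=3)[3] == pytest.approx(0.5)
        assert not apply_E1(pclass, ptime, N=3)[3]

    def test_never_adds_positives(self):
        r = np.random.default_rng(0)
        pclass = r.random(200)
        ptime = r.random(200)
        flags = apply_E1(pclass, ptime, N=3)
        assert not np.any(flags & ~(pclass > 0.5))


class TestMinuteSmooth:
    def test_four_of_six_is_eating(self):
        assert minute_smooth([1, 1, 1, 1, 0, 0]).tolist() == [True]

    def test_exactly_three_of_six_is_not(self):
        assert minute_smooth([1, 1, 1, 0, 0, 0]).tolist() == [False]

    def test_all_negative(self):
        assert minute_smooth([0] * 12).tolist() == [False, False]

    def test_blocks_anchored_at_start(self):
        flags = [0] * 6 + [1, 1, 1, 1, 1, 0]
        assert minute_smooth(flags).tolist() == [False, True]


class TestE2:
    def test_four_minute_run_deleted(self):
        flags = [False] * 3 + [True] * 4 + [False] * 5
        assert apply_E2(flags, 5) == []

    def test_five_minute_run_kept(self):
        flags = [False] * 3 + [True] * 5 + [False] * 4
        assert apply_E2(flags, 5) == [(3, 8)]

    def test_split_runs_both_deleted(self):
        flags = [True] * 3 + [False] + [True] * 3
        assert apply_E2(flags, 5) == []

    def test_idempotent_and_min_length(self):
        r = np.random.default_rng(1)
        flags = r.random(120) > 0.5
        meals = apply_E2(flags, 5)
        assert all(e - s >= 5 for s, e in meals)
        # rebuild flags from the output: a second pass changes nothing
        rebuilt = np.zeros(120, bool)
        for s, e in meals:
            rebuilt[s:e] = True
        assert apply_E2(rebuilt, 5) == meals

    def test_run_reaching_stream_end_kept(self):
        flags = [False] * 2 + [True] * 6
        assert apply_E2(flags, 5) == [(2, 8)]


class TestE3:
    def test_stationary_stream_energy_zero(self):
        acc_mag = np.full(1000, 9.80665)
        e = energy_signal(acc_mag, 50.0)
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_meal_with_burst_kept_without_burst_rejected(self):
        fs = 50.0
        n = int(20 * 60 * fs)
        r = np.random.default_rng(2)
        quiet = 9.80665 + 0.05 * r.standard_normal(n)
        burst = quiet.copy()
        b0 = int(4 * 60 * fs)
        burst[b0 : b0 + int(10 * fs)] += 3.0 * r.standard_normal(int(10 * fs))
        meals = [(5, 12)]  # minutes
        e_burst = energy_signal(burst, fs)
        e_quiet = energy_signal(quiet, fs)
        assert apply_E3(meals, e_burst, fs, lookback_s=120.0, k=3.0) == meals
        assert apply_E3(meals, e_quiet, fs, lookback_s=120.0, k=3.0) == []


class TestD1:
    def _mag_with_peaks(self, n=500, peaks=(100, 300), height=150.0):
        mag = np.abs(np.random.default_rng(3).standard_normal(n)) * 2
        for p in peaks:
            mag[p - 5 : p + 5] += height
        return mag

    def test_window_with_peaks_kept(self):
        mag = self._mag_with_peaks()
        out = apply_D1([Window(0, 500, "DFW")], np.array([0.9]), mag, 50.0)
        assert len(out) == 1
        assert out[0][:2] == (0.0, 10.0)

    def test_flat_window_dropped(self):
        mag = np.full(500, 1.0)
        out = apply_D1([Window(0, 500, "DFW")], np.array([0.9]), mag, 50.0)
        assert out == []

    def test_threshold_above_global_max_drops_all(self):
        mag = self._mag_with_peaks()
        out = apply_D1(
            [Window(0, 500, "DFW")], np.array([0.9]), mag, 50.0,
            peak_thresh=mag.max() + 1,
        )
        assert out == []

    def test_negative_windows_ignored(self):
        mag = self._mag_with_peaks()
        out = apply_D1([Window(0, 500, "DFW")], np.array([0.2]), mag, 50.0)
        assert out == []


class TestFuse:
    def test_no_events_all_other(self):
        assert fuse([], [], 6) == ["other"] * 6

    def test_sip_inside_meal_precedence(self):
        meals = [(0, 10)]  # minutes 0-10 -> units 0-60
        drinks = [(25.0, 32.0, 0.9)]
        units = fuse(meals, drinks, 60)
        assert units[2] == "drink" and units[3] == "drink"
        assert units[1] == "eat" and units[4] == "eat"

    def test_unit_count(self):
        units = fuse([(0, 5)], [], 13)
        assert len(units) == 13


class TestWindowsToUnits:
    def test_non_overlapping_windows_identity(self):
        ws = [Window(i * 500, (i + 1) * 500, "FW") for i in range(6)]
        vals = np.array([0, 1, 0, 1, 1, 0])
        out = windows_to_units(ws, vals, 50.0, 3000)
        np.testing.assert_array_equal(out, vals)

    def test_overlapping_windows_nearest_center(self):
        # stride 375 @50 Hz: window k center = (250 + 375k)/50 s
        ws = [Window(i * 375, i * 375 + 500, "FW") for i in range(7)]
        vals = np.arange(7)
        out = windows_to_units(ws, vals, 50.0, 3000)
        assert len(out) == 6
        assert out[0] == 0 and out[-1] in (5, 6)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_restriction_layer_monotone(seed):
    """E1 + minute smoothing + E2 never yields more eating time than raw
    classification followed by minute smoothing alone."""
    r = np.random.default_rng(seed)
    n = 240
    pclass = r.random(n)
    ptime = MealProbabilityProfile()(np.linspace(6, 22, n))
    raw_minutes = minute_smooth(pclass > 0.5)
    gated_minutes = minute_smooth(apply_E1(pclass, ptime))
    meals = apply_E2(gated_minutes, 5)
    restricted = sum(e - s for s, e in meals)
    assert restricted <= int(raw_minutes.sum())
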