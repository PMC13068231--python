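"""Diary feature engineering and the rolling 28-day persona."""

import numpy as np
import pytest

from drinknudge.persona import (
    DEFAULT_CONFIG,
    build_persona,
    binge_episodes,
    drink_free_days,
    feature_registry,
    longest_consumption_streak,
    longest_drink_free_streak,
    weekly_units,
)
from drinknudge.records import MINUTES_PER_DAY, AppEvent, DiaryEntry, EventKind

from conftest import events_on_days, make_history


# -- brute-force oracles (run scans by exhaustive enumeration) --------------


def brute_binge(units, threshold=6.0, min_days=3):
    """Count maximal runs of days > threshold with length >= min_days by
    checking every (start, end) sub-run explicitly."""
    n = len(units)
    episodes = 0
    for start in range(n):
        for end in range(start + min_days, n + 1):
            all_qualify = all(u > threshold for u in units[start:end])
            left_maximal = start == 0 or units[start - 1] <= threshold
            right_maximal = end == n or units[end] <= threshold
            if all_qualify and left_maximal and right_maximal:
                episodes += 1
    return episodes


def brute_longest(units, predicate):
    best = 0
    for start in range(len(units)):
        for end in range(start, len(units)):
            if all(predicate(u) for u in units[start : end + 1]):
                best = max(best, end - start + 1)
    return best


class TestWeeklyUnits:
    def test_empty_diary_is_zero(self):
        assert weekly_units(make_history([]), 1) == 0.0

    def test_hand_sum(self):
        h = make_history([3.0, None, None, None, 11.5])
        assert weekly_units(h, 1) == pytest.approx(14.5)

    def test_constant_week(self):
        assert weekly_units(make_history([2.0] * 7), 1) == pytest.approx(14.0)

    def test_signup_anchoring(self):
        h = make_history([1.0] * 14, signup_day=5)
        assert weekly_units(h, 2) == pytest.approx(7.0)

    def test_invalid_week_rejected(self):
        with pytest.raises(ValueError):
            weekly_units(make_history([]), 0)


class TestRunFeatures:
    @pytest.mark.parametrize(
        "units, expected",
        [
            ([5, 6, 6, 2, 0], 0),  # never strictly above 6
            ([7, 7, 7], 1),
            ([7, 7, 0, 7, 7, 7, 7], 1),
            ([7, 7, 7, 0, 8, 8, 8], 2),
            ([7, 7], 0),
        ],
    )
    def test_binge_examples(self, units, expected):
        h = make_history(units)
        assert binge_episodes(h, (0, len(units))) == expected

    def test_no_entries_is_all_drink_free(self):
        assert longest_drink_free_streak(make_history([]), (0, 28)) == 28

    def test_streak_run_scan(self):
        h = make_history([0, 0, 5, 0, 0, 0])
        assert longest_drink_free_streak(h, (0, 6)) == 3

    def test_every_day_drinking_has_no_streak(self):
        h = make_history([1] * 10)
        assert longest_drink_free_streak(h, (0, 10)) == 0

    def test_matches_bruteforce_on_random_sequences(self, rng):
        """Run-detection agrees with exhaustive enumeration on random
        28-day unit sequences."""
        for _ in range(200):
            units = np.round(rng.gamma(1.2, 4.0, size=28) * rng.integers(0, 2, size=28), 1)
            h = make_history(list(units))
            window = (0, 28)
            assert binge_episodes(h, window) == brute_binge(units)
            assert longest_drink_free_streak(h, window) == brute_longest(units, lambda u: u == 0)
            assert longest_consumption_streak(h, window) == brute_longest(units, lambda u: u > 0)
            assert drink_free_days(h, window) == sum(1 for u in units if u == 0)


class TestPersona:
    AS_OF = 28 * MINUTES_PER_DAY

    def test_registry_is_fixed_length(self):
        names = feature_registry()
        h = make_history([2.0] * 28, events=events_on_days([1, 5, 9]))
        p = build_persona(h, self.AS_OF)
        assert len(p) == len(names)
        assert len(set(names)) == len(names)

    def test_unavailable_without_engagement(self):
        h = make_history([2.0] * 28)
        assert build_persona(h, self.AS_OF).available is False

    def test_available_with_minimum_events(self):
        h = make_history([2.0] * 28, events=events_on_days([1, 5, 9]))
        assert build_persona(h, self.AS_OF).available is True

    def test_deterministic(self):
        h = make_history([2.0] * 28, events=events_on_days([1, 5, 9]))
        a = build_persona(h, self.AS_OF)
        b = build_persona(h, self.AS_OF)
        np.testing.assert_array_equal(a.values, b.values)

    def test_translation_invariance(self):
        """Shifting every timestamp and as_of by the same whole number of
        weeks leaves the vector unchanged."""
        shift_days = 7 * 13
        base = make_history([0, 3, 9, 0, 2, 7, 7] * 4, events=events_on_days([2, 8, 15, 22]))
        shifted = make_history(
            [0, 3, 9, 0, 2, 7, 7] * 4,
            signup_day=shift_days,
            events=events_on_days([2, 8, 15, 22], signup_day=shift_days),
        )
        a = build_persona(base, self.AS_OF)
        b = build_persona(shifted, self.AS_OF + shift_days * MINUTES_PER_DAY)
        np.testing.assert_allclose(a.values, b.values)

    def test_window_locality(self):
        """Records strictly older than the 28-day window never matter."""
        recent_units = [0, 3, 9, 0, 2, 7, 7] * 4
        h = make_history(recent_units, signup_day=0, events=events_on_days([2, 8, 15]))
        as_of = self.AS_OF
        h_old = make_history(recent_units, signup_day=0, events=events_on_days([2, 8, 15]))
        h_old.diary.insert(0, DiaryEntry(day=-3, units=40.0))
        h_old.events.insert(
            0, AppEvent(minute=-5 * MINUTES_PER_DAY, kind=EventKind.page_view, duration_s=60)
        )
        np.testing.assert_allclose(
            build_persona(h, as_of).values, build_persona(h_old, as_of).values
        )

    def test_identical_weeks_zero_trends(self):
        """When two consecutive weeks are behaviorally identical, every
        change-trend entry is exactly zero."""
        week = [0, 4, 8, 0, 2, 7, 7]
        h = make_history(week * 4, events=events_on_days([1, 8, 15, 22], hour=10))
        p = build_persona(h, self.AS_OF)
        names = feature_registry()
        trends = [v for n, v in zip(names, p.values) if n.startswith("trend_")]
        assert trends and all(v == 0.0 for v in trends)

    def test_latency_capped(self):
        """Notification-to-engagement latency never exceeds the 168 h cap."""
        from drinknudge.records import NotificationCategory, NotificationRecord

        h = make_history([1.0] * 28, events=events_on_days([1, 2, 3]))
        h.notifications.append(
            NotificationRecord(minute=2 * MINUTES_PER_DAY, category=NotificationCategory.generic)
        )
        names = feature_registry()
        p = build_persona(h, self.AS_OF)
        latency = p.values[names.index("mean_engagement_latency_h")]
        assert 0.0 <= latency <= DEFAULT_CONFIG.latency_cap_h

    def test_as_of_before_signup_rejected(self):
        h = make_history([1.0], signup_day=10)
        with pytest.raises(ValueError):
            build_persona(h, 0)
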