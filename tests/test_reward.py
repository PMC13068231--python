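"""Reward bands, trigger extraction, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drinknudge.records import (
    MINUTES_PER_DAY,
    AppEvent,
    EventKind,
    NotificationCategory,
    NotificationRecord,
)
from drinknudge.reward import (
    ENGAGEMENT_KINDS,
    PENALTY_KINDS,
    REDUCTION_KINDS,
    RewardEvent,
    RewardKind,
    RewardSpec,
    compute_reward,
    derive_reward_events,
)

from conftest import make_history

SPEC = RewardSpec()


def band_of(kind: RewardKind, spec: RewardSpec = SPEC):
    if kind in ENGAGEMENT_KINDS:
        return spec.engagement_band
    if kind in REDUCTION_KINDS:
        return spec.reduction_band
    return spec.penalty_band


class TestComputeReward:
    def test_empty_is_zero(self):
        assert compute_reward([]) == 0.0

    @pytest.mark.parametrize("kind", list(RewardKind))
    @pytest.mark.parametrize("magnitude", [0.0, 0.5, 1.0, 3.7, 5.0, 50.0])
    def test_single_component_stays_in_band(self, kind, magnitude):
        lo, hi = band_of(kind)
        r = compute_reward([RewardEvent(kind, magnitude)])
        assert lo <= r <= hi

    def test_larger_reduction_earns_more(self):
        small = compute_reward([RewardEvent(RewardKind.weekly_units_decreased, 1.0)])
        large = compute_reward([RewardEvent(RewardKind.weekly_units_decreased, 4.0)])
        assert large > small

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            RewardEvent(RewardKind.engaged_within_window, -1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(RewardKind)),
                st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
            ),
            max_size=12,
        )
    )
    def test_total_bounded_by_band_extremes(self, raw):
        """No component ever escapes its band, so the total is bounded by
        the sum of band extremes of the constituent events."""
        events = [RewardEvent(k, m) for k, m in raw]
        total = compute_reward(events)
        lo = sum(band_of(e.kind)[0] for e in events)
        hi = sum(band_of(e.kind)[1] for e in events)
        assert lo - 1e-9 <= total <= hi + 1e-9

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(RewardKind)),
                st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
            ),
            max_size=8,
        ),
        st.randoms(),
    )
    def test_permutation_invariant(self, raw, rnd):
        events = [RewardEvent(k, m) for k, m in raw]
        shuffled = list(events)
        rnd.shuffle(shuffled)
        assert compute_reward(events) == pytest.approx(compute_reward(shuffled))

    def test_monotone_in_added_events(self):
        base = [RewardEvent(RewardKind.engaged_within_window, 1.0)]
        with_positive = base + [RewardEvent(RewardKind.weekly_units_decreased, 2.0)]
        with_penalty = base + [RewardEvent(RewardKind.disengaged_after_multiple, 3.0)]
        assert compute_reward(with_positive) >= compute_reward(base)
        assert compute_reward(with_penalty) <= compute_reward(base)

    def test_unknown_kind_rejected(self):
        class Fake:
            kind = "made_up"
            magnitude = 1.0

        with pytest.raises(ValueError):
            compute_reward([Fake()])


def notification(minute, **kw):
    return NotificationRecord(minute=minute, category=NotificationCategory.personalized, **kw)


class TestDeriveRewardEvents:
    def test_app_open_within_hour_engages(self):
        h = make_history([1.0] * 14)
        note = notification(minute=MINUTES_PER_DAY)
        h.events.append(AppEvent(minute=note.minute + 30, kind=EventKind.session_start))
        kinds = {e.kind for e in derive_reward_events(h, note)}
        assert RewardKind.engaged_within_window in kinds

    def test_late_open_does_not_engage(self):
        h = make_history([1.0] * 14)
        note = notification(minute=MINUTES_PER_DAY)
        h.events.append(AppEvent(minute=note.minute + 120, kind=EventKind.session_start))
        kinds = {e.kind for e in derive_reward_events(h, note)}
        assert RewardKind.engaged_within_window not in kinds

    def test_weekly_change_triggers(self):
        # week 1: 28 units, week 2: 14 units -> decrease trigger in week 2
        h = make_history([4.0] * 7 + [2.0] * 7)
        note = notification(minute=8 * MINUTES_PER_DAY)
        events = derive_reward_events(h, note)
        decreased = [e for e in events if e.kind == RewardKind.weekly_units_decreased]
        assert len(decreased) == 1
        assert decreased[0].magnitude == pytest.approx(14.0)

    def test_three_ignored_notifications_trigger_disengagement(self):
        """A hand-traced fixture: three consecutive unengaged notifications
        with the threshold at 3 fires the fatigue penalty."""
        h = make_history([1.0] * 14)
        for d in (1, 2, 3):
            h.notifications.append(
                NotificationRecord(
                    minute=d * MINUTES_PER_DAY,
                    category=NotificationCategory.personalized,
                    engaged_within_1h=False,
                )
            )
        note = h.notifications[-1]
        kinds = {e.kind for e in derive_reward_events(h, note)}
        assert RewardKind.disengaged_after_multiple in kinds

    def test_two_ignored_notifications_do_not_trigger(self):
        h = make_history([1.0] * 14)
        for d in (1, 2):
            h.notifications.append(
                NotificationRecord(
                    minute=d * MINUTES_PER_DAY,
                    category=NotificationCategory.personalized,
                    engaged_within_1h=False,
                )
            )
        kinds = {e.kind for e in derive_reward_events(h, h.notifications[-1])}
        assert RewardKind.disengaged_after_multiple not in kinds

    def test_drink_free_increase_trigger(self):
        # week 1: all days drinking; week 2: three drink-free days
        h = make_history([3.0] * 7 + [3.0, 0, 3.0, 0, 3.0, 0, 3.0])
        h2 = make_history([3.0] * 7 + [3.0, None, 3.0, None, 3.0, None, 3.0])
        for hist in (h, h2):
            note = notification(minute=9 * MINUTES_PER_DAY)
            events = derive_reward_events(hist, note)
            dfd = [e for e in events if e.kind == RewardKind.drink_free_days_increased]
            assert dfd and dfd[0].magnitude == pytest.approx(3.0)
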