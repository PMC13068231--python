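"""The reinforcement signal: mapping post-notification behavior to rewards.

Three bands, mirroring the deployed rule set:

* **engagement** (+1 to +10) — app interaction shortly after a message,
  e.g. opening the app within 1 hour of a notification, or completing a
  goal after an encouragement message;
* **reduction** (+10 to +20) — reductions in weekly alcohol consumption or
  increases in drink-free days;
* **penalty** (−10 to −5) — disengagement after multiple consecutive
  notifications (message fatigue), increased consumption, or a shifted
  drinking pattern.

Within a band, placement is a linear ramp in the event's magnitude (units
reduced, consecutive notifications ignored, ...) saturating at the band's
far end; components from simultaneous triggers add.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .records import (
    DAYS_PER_WEEK,
    MINUTES_PER_HOUR,
    NotificationRecord,
    UserHistory,
)
from .persona import drink_free_days, weekly_units

__all__ = ["RewardKind", "RewardEvent", "RewardSpec", "compute_reward", "derive_reward_events"]


class RewardKind(str, Enum):
    engaged_within_window = "engaged_within_window"
    goal_completed_after_encouragement = "goal_completed_after_encouragement"
    weekly_units_decreased = "weekly_units_decreased"
    drink_free_days_increased = "drink_free_days_increased"
    disengaged_after_multiple = "disengaged_after_multiple"
    weekly_units_increased = "weekly_units_increased"
    drinking_pattern_changed = "drinking_pattern_changed"


ENGAGEMENT_KINDS = frozenset(
    {RewardKind.engaged_within_window, RewardKind.goal_completed_after_encouragement}
)
REDUCTION_KINDS = frozenset(
    {RewardKind.weekly_units_decreased, RewardKind.drink_free_days_increased}
)
PENALTY_KINDS = frozenset(
    {
        RewardKind.disengaged_after_multiple,
        RewardKind.weekly_units_increased,
        RewardKind.drinking_pattern_changed,
    }
)


@dataclass(frozen=True)
class RewardEvent:
    kind: RewardKind
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass(frozen=True)
class RewardSpec:
    """Band edges and trigger parameters, serialized with each run config."""

    engagement_band: tuple[float, float] = (1.0, 10.0)
    reduction_band: tuple[float, float] = (10.0, 20.0)
    penalty_band: tuple[float, float] = (-10.0, -5.0)
    engagement_window_h: float = 1.0
    disengagement_min_notifications: int = 3
    #: magnitude at which a component saturates at its band's far end
    ramp_scale: float = 5.0
    #: weekday<->weekend consumption-share shift counted as a pattern change
    pattern_shift_fraction: float = 0.25

    def __post_init__(self) -> None:
        for band in (self.engagement_band, self.reduction_band, self.penalty_band):
            if band[0] > band[1]:
                raise ValueError(f"band low > high: {band}")
        if self.engagement_band[0] <= 0:
            raise ValueError("engagement band must be positive")
        if self.penalty_band[1] >= 0:
            raise ValueError("penalty band must be negative")


def _component(kind: RewardKind, magnitude: float, spec: RewardSpec) -> float:
    frac = min(magnitude / spec.ramp_scale, 1.0)
    if kind in ENGAGEMENT_KINDS:
        lo, hi = spec.engagement_band
        return lo + frac * (hi - lo)
    if kind in REDUCTION_KINDS:
        lo, hi = spec.reduction_band
        return lo + frac * (hi - lo)
    if kind in PENALTY_KINDS:
        lo, hi = spec.penalty_band  # lo more negative than hi
        return hi + frac * (lo - hi)
    raise ValueError(f"unknown reward event kind: {kind}")


def compute_reward(events, spec: RewardSpec = RewardSpec()) -> float:
    """Sum of band-clamped per-event components; empty collection gives 0."""
    total = 0.0
    for ev in events:
        kind = RewardKind(ev.kind)
        total += _component(kind, ev.magnitude, spec)
    return total


def derive_reward_events(
    history: UserHistory,
    notification: NotificationRecord,
    spec: RewardSpec = RewardSpec(),
) -> list[RewardEvent]:
    """Extract the triggered reward events for one notification.

    Engagement is any app event within ``engagement_window_h`` of the
    notification. Consumption triggers compare the completed study week
    containing/after the notification to the week before it. Disengagement
    fires when the most recent ``disengagement_min_notifications``
    notifications (including this one) all went unengaged.
    """
    events: list[RewardEvent] = []
    window_min = spec.engagement_window_h * MINUTES_PER_HOUR
    engaged = any(
        notification.minute <= ev.minute < notification.minute + window_min
        for ev in history.events
    )
    if engaged:
        events.append(RewardEvent(RewardKind.engaged_within_window, 1.0))
        goal_done = any(
            ev.kind.value == "goal_view"
            and notification.minute <= ev.minute < notification.minute + window_min
            for ev in history.events
        )
        if notification.bct_tag == "goal_setting" and goal_done:
            events.append(RewardEvent(RewardKind.goal_completed_after_encouragement, 1.0))

    # week containing the notification, signup-anchored
    rel_day = notification.minute // (24 * MINUTES_PER_HOUR) - history.signup_day
    week = rel_day // DAYS_PER_WEEK + 1
    if week >= 2:
        cur = weekly_units(history, week)
        prev = weekly_units(history, week - 1)
        if cur < prev:
            events.append(RewardEvent(RewardKind.weekly_units_decreased, prev - cur))
        elif cur > prev:
            events.append(RewardEvent(RewardKind.weekly_units_increased, cur - prev))

        w0 = history.signup_day + DAYS_PER_WEEK * (week - 1)
        dfd_cur = drink_free_days(history, (w0, w0 + DAYS_PER_WEEK))
        dfd_prev = drink_free_days(history, (w0 - DAYS_PER_WEEK, w0))
        if dfd_cur > dfd_prev:
            events.append(
                RewardEvent(RewardKind.drink_free_days_increased, float(dfd_cur - dfd_prev))
            )

        shift = _weekend_share_shift(history, week)
        if shift > spec.pattern_shift_fraction:
            events.append(RewardEvent(RewardKind.drinking_pattern_changed, shift))

    recent = [n for n in history.sorted_notifications() if n.minute <= notification.minute]
    k = spec.disengagement_min_notifications
    if len(recent) >= k and all(not n.engaged_within_1h for n in recent[-k:]) and not engaged:
        events.append(RewardEvent(RewardKind.disengaged_after_multiple, float(k)))
    return events


def _weekend_share_shift(history: UserHistory, week: int) -> float:
    """Absolute change in the weekend share of weekly consumption vs prior week."""

    def share(w: int) -> float:
        start = history.signup_day + DAYS_PER_WEEK * (w - 1)
        days = np.arange(start, start + DAYS_PER_WEEK)
        per_day = np.zeros(DAYS_PER_WEEK)
        for d, u in history.day_units().items():
            if start <= d < start + DAYS_PER_WEEK:
                per_day[d - start] += u
        total = per_day.sum()
        if total == 0:
            return 0.0
        return float(per_day[days % 7 >= 5].sum() / total)

    return abs(share(week) - share(week - 1))
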