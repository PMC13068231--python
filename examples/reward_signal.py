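"""Derive the reinforcement signal for one notification.

A user gets a personalized message, opens the app 25 minutes later, and
their diary shows this week down 6 units on last week. The reward
combines an engagement component (band +1..+10) and a consumption-
reduction component (band +10..+20).
"""

from drinknudge.records import (
    MINUTES_PER_DAY,
    AppEvent,
    Demographics,
    DiaryEntry,
    EventKind,
    Gender,
    NotificationCategory,
    NotificationRecord,
    ServiceBranch,
    UserHistory,
)
from drinknudge.reward import RewardSpec, compute_reward, derive_reward_events

history = UserHistory(
    user_id="demo",
    signup_minute=0,
    demographics=Demographics(
        age=40.0,
        gender=Gender.female,
        service_branch=ServiceBranch.royal_navy,
        service_length=8.0,
        prior_alcohol_treatment=True,
    ),
)
# week 1: 24 units; week 2: 18 units (6-unit reduction)
for day, units in enumerate([4, 4, 0, 4, 4, 4, 4, 3, 3, 0, 3, 3, 3, 3]):
    if units:
        history.diary.append(DiaryEntry(day=day, units=float(units)))

notification = NotificationRecord(
    minute=8 * MINUTES_PER_DAY + 19 * 60,  # week-2 evening message
    category=NotificationCategory.personalized,
    segment_id="per_feedback",
    bct_tag="feedback_on_behavior",
)
history.notifications.append(notification)
history.events.append(
    AppEvent(minute=notification.minute + 25, kind=EventKind.session_start)
)

spec = RewardSpec()
events = derive_reward_events(history, notification, spec)
for ev in events:
    print(f"trigger: {ev.kind.value:28s} magnitude {ev.magnitude:.1f}")
reward = compute_reward(events, spec)
print(f"\ntotal reward: {reward:.2f}")
print(
    "Engagement within 1 h maps into [1, 10]; a 6-unit weekly reduction"
    "\nsaturates the [10, 20] band, so the total rewards both behaviors."
)
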