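"""Build the rolling 28-day adaptive persona for one hand-crafted user.

Constructs a month of diary and app-event history, assembles the persona
vector, and prints a handful of named features. The vector is the state
the reinforcement-learning agent conditions on; `available=False` would
mean the user engaged too little for personalization and generic
messaging applies instead.
"""

from drinknudge.persona import build_persona, feature_registry
from drinknudge.records import (
    MINUTES_PER_DAY,
    AppEvent,
    Demographics,
    DiaryEntry,
    EventKind,
    Gender,
    ServiceBranch,
    UserHistory,
)

history = UserHistory(
    user_id="demo",
    signup_minute=0,
    demographics=Demographics(
        age=52.0,
        gender=Gender.male,
        service_branch=ServiceBranch.army,
        service_length=14.0,
        prior_alcohol_treatment=False,
    ),
)

# four weeks: heavy weekends, a mid-month binge run, easing off in week 4
units_by_day = [0, 4, 0, 0, 6, 12, 10,
                0, 3, 0, 0, 7, 11, 9,
                8, 8, 7, 0, 0, 9, 8,
                0, 2, 0, 0, 0, 6, 5]
for day, units in enumerate(units_by_day):
    if units > 0:
        history.diary.append(DiaryEntry(day=day, units=float(units)))
for day in (1, 4, 8, 12, 15, 19, 22, 26):  # app opens roughly twice a week
    history.events.append(
        AppEvent(minute=day * MINUTES_PER_DAY + 20 * 60, kind=EventKind.session_start)
    )

persona = build_persona(history, as_of=28 * MINUTES_PER_DAY)
names = feature_registry()
print(f"persona available: {persona.available}; vector length: {len(persona)}")
for feature in (
    "weekly_units",
    "binge_episodes",
    "drink_free_days",
    "longest_drink_free_streak",
    "weekend_drinking_days",
    "n_sessions_28d",
    "trend_weekly_units",
):
    print(f"  {feature:28s} = {persona.values[names.index(feature)]:8.2f}")
print(
    "\nweekly_units is the last-7-day diary total; trend_weekly_units is that"
    "\nweek minus the week before (negative = drinking less); binge_episodes"
    "\ncounts runs of 3+ consecutive days above 6 units in the 28-day window."
)
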