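import numpy as np
import pytest

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


def make_demographics(**overrides) -> Demographics:
    base = dict(
        age=45.0,
        gender=Gender.male,
        service_branch=ServiceBranch.army,
        service_length=12.0,
        prior_alcohol_treatment=False,
    )
    base.update(overrides)
    return Demographics(**base)


def make_history(
    day_units=None,
    signup_day: int = 0,
    events=None,
    user_id: str = "u1",
    **demo_overrides,
) -> UserHistory:
    """Build a history whose diary is given as units-per-day starting at
    the signup day (None entries are skipped entirely)."""
    h = UserHistory(
        user_id=user_id,
        signup_minute=signup_day * MINUTES_PER_DAY,
        demographics=make_demographics(**demo_overrides),
    )
    for offset, units in enumerate(day_units or []):
        if units is None:
            continue
        h.diary.append(DiaryEntry(day=signup_day + offset, units=float(units)))
    h.events.extend(events or [])
    return h


def events_on_days(days, signup_day=0, kind=EventKind.session_start, hour=10):
    return [
        AppEvent(minute=(signup_day + d) * MINUTES_PER_DAY + hour * 60, kind=kind) for d in days
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
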