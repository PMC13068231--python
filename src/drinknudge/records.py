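"""Core record types shared across the pipeline.

Time convention: simulated time is an integer **minute** offset from the
trial epoch. A day is ``minute // 1440``; weeks are 7-day blocks anchored at
the user's signup day (signup day = user-relative day 0), half-open
``[7*(w-1), 7*w)`` for week ``w >= 1``. Day-of-week is ``day % 7`` with the
epoch anchored on a Monday, so days 5 and 6 of each block are the weekend.
ISO-8601 conversion happens only at the I/O boundary (:mod:`drinknudge.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

MINUTES_PER_DAY = 1440
MINUTES_PER_HOUR = 60
DAYS_PER_WEEK = 7


class EventKind(str, Enum):
    """Closed enumeration of in-app interaction events."""

    session_start = "session_start"
    page_view = "page_view"
    goal_view = "goal_view"
    message_interaction = "message_interaction"
    questionnaire_submit = "questionnaire_submit"


class Gender(str, Enum):
    male = "male"
    female = "female"


class ServiceBranch(str, Enum):
    army = "army"
    royal_air_force = "royal_air_force"
    royal_navy = "royal_navy"


class NotificationCategory(str, Enum):
    """Message categories the agent chooses among, plus scheduled kinds.

    The first four are the agent's action space; ``questionnaire_prompt`` and
    ``reminder`` are fixed-schedule notifications both arms receive.
    """

    no_message = "no_message"
    generic = "generic"
    personalized = "personalized"
    personalized_event = "personalized_event"
    questionnaire_prompt = "questionnaire_prompt"
    reminder = "reminder"


#: The agent-selectable categories, in fixed order (Q-network output order).
ACTION_CATEGORIES = (
    NotificationCategory.no_message,
    NotificationCategory.generic,
    NotificationCategory.personalized,
    NotificationCategory.personalized_event,
)


@dataclass(frozen=True)
class DiaryEntry:
    """One user-day of logged alcohol consumption (UK units; 1 unit = 8 g)."""

    day: int
    units: float

    def __post_init__(self) -> None:
        if self.units < 0:
            raise ValueError(f"units must be >= 0, got {self.units}")


@dataclass(frozen=True)
class AppEvent:
    minute: int
    kind: EventKind
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Weekly self-report; scores arrive as plain numbers (no item logic)."""

    week_index: int
    depression: float
    anxiety: float
    loneliness: float


@dataclass(frozen=True)
class NotificationRecord:
    """A delivered push notification and whether it led to engagement."""

    minute: int
    category: NotificationCategory
    segment_id: Optional[str] = None
    engaged_within_1h: bool = False
    bct_tag: Optional[str] = None


@dataclass
class Demographics:
    age: float
    gender: Gender
    service_branch: ServiceBranch
    service_length: float
    prior_alcohol_treatment: bool
    is_veteran: bool = True
    complete: bool = True


@dataclass
class UserHistory:
    """Everything recorded for one user: the raw material of personas and rewards."""

    user_id: str
    signup_minute: int
    demographics: Demographics
    diary: list[DiaryEntry] = field(default_factory=list)
    events: list[AppEvent] = field(default_factory=list)
    questionnaires: list[QuestionnaireResponse] = field(default_factory=list)
    notifications: list[NotificationRecord] = field(default_factory=list)

    @property
    def signup_day(self) -> int:
        return self.signup_minute // MINUTES_PER_DAY

    def day_units(self) -> dict[int, float]:
        """Total units per absolute day (multiple entries on a day are summed)."""
        totals: dict[int, float] = {}
        for entry in self.diary:
            totals[entry.day] = totals.get(entry.day, 0.0) + entry.units
        return totals

    def sorted_events(self) -> list[AppEvent]:
        return sorted(self.events, key=lambda e: e.minute)

    def sorted_notifications(self) -> list[NotificationRecord]:
        return sorted(self.notifications, key=lambda n: n.minute)
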