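"""Synthetic veteran-user cohort and week-by-week behavior simulation.

The generator stands in for two things no public data can provide: the
synthetic training corpus the agent learns from, and a realistic cohort on
which the 12-week two-arm trial can be exercised end to end. It emulates
the qualitative shapes that matter for testing the pipeline — heavy
baseline drinking (most users above the 14-unit UK weekly guideline),
multiplicative week-on-week decline in consumption and app usage,
notification responsiveness that differs by message category and decays
with notification fatigue, weekly attrition, and mood self-reports — and
makes no claim of behavioral realism beyond those shapes.

Four named archetypes span the engagement spectrum:

* ``responsive_reducer`` — engages often, responds well to personalized
  content, reduces steadily;
* ``notification_fatigued`` — starts engaged but fatigues quickly under
  notification volume;
* ``steady_heavy`` — heavy, stable consumption, sparse app use;
* ``early_dropout`` — high weekly attrition hazard, rarely retained.

All randomness flows from the seed in :class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .records import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    AppEvent,
    Demographics,
    DiaryEntry,
    EventKind,
    Gender,
    NotificationCategory,
    NotificationRecord,
    QuestionnaireResponse,
    ServiceBranch,
    UserHistory,
)

__all__ = [
    "UserArchetype",
    "ARCHETYPES",
    "DemographicTargets",
    "CohortConfig",
    "UserSeed",
    "UserState",
    "WeekResult",
    "generate_cohort",
    "step_week",
    "history_from_seed",
]


@dataclass(frozen=True)
class UserArchetype:
    name: str
    weekly_decline_rate: float
    #: probability of engaging within 1 h of a notification, per category
    responsiveness: dict[NotificationCategory, float]
    #: multiplicative consumption factor applied on engagement, per category
    category_effect: dict[NotificationCategory, float]
    #: each successive notification in a week multiplies engagement
    #: probability by (1 - fatigue_rate)
    fatigue_rate: float
    attrition_hazard: float
    base_events_per_week: float
    usage_decline_rate: float
    questionnaire_prob: float
    mood_mean: float = 8.0
    mood_sd: float = 3.0

    def __post_init__(self) -> None:
        for p in list(self.responsiveness.values()) + [
            self.fatigue_rate,
            self.attrition_hazard,
            self.questionnaire_prob,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")


def _resp(generic: float, personalized: float, event: float) -> dict[NotificationCategory, float]:
    return {
        NotificationCategory.no_message: 0.0,
        NotificationCategory.generic: generic,
        NotificationCategory.personalized: personalized,
        NotificationCategory.personalized_event: event,
        NotificationCategory.questionnaire_prompt: generic,
        NotificationCategory.reminder: generic * 0.7,
    }


def _effect(generic: float, personalized: float, event: float) -> dict[NotificationCategory, float]:
    eff = {c: 1.0 for c in NotificationCategory}
    eff[NotificationCategory.generic] = generic
    eff[NotificationCategory.personalized] = personalized
    eff[NotificationCategory.personalized_event] = event
    return eff


ARCHETYPES: dict[str, UserArchetype] = {
    "responsive_reducer": UserArchetype(
        name="responsive_reducer",
        weekly_decline_rate=0.94,
        responsiveness=_resp(0.35, 0.55, 0.60),
        category_effect=_effect(0.99, 0.96, 0.95),
        fatigue_rate=0.05,
        attrition_hazard=0.03,
        base_events_per_week=8.0,
        usage_decline_rate=0.97,
        questionnaire_prob=0.85,
        mood_mean=7.0,
    ),
    "notification_fatigued": UserArchetype(
        name="notification_fatigued",
        weekly_decline_rate=0.96,
        responsiveness=_resp(0.30, 0.40, 0.45),
        category_effect=_effect(0.995, 0.975, 0.97),
        fatigue_rate=0.35,
        attrition_hazard=0.10,
        base_events_per_week=5.0,
        usage_decline_rate=0.88,
        questionnaire_prob=0.6,
        mood_mean=10.0,
    ),
    "steady_heavy": UserArchetype(
        name="steady_heavy",
        weekly_decline_rate=0.995,
        responsiveness=_resp(0.15, 0.22, 0.25),
        category_effect=_effect(1.0, 0.99, 0.985),
        fatigue_rate=0.15,
        attrition_hazard=0.08,
        base_events_per_week=2.2,
        usage_decline_rate=0.95,
        questionnaire_prob=0.4,
        mood_mean=12.0,
    ),
    "early_dropout": UserArchetype(
        name="early_dropout",
        weekly_decline_rate=0.97,
        responsiveness=_resp(0.2, 0.3, 0.3),
        category_effect=_effect(1.0, 0.99, 0.99),
        fatigue_rate=0.25,
        attrition_hazard=0.40,
        base_events_per_week=4.0,
        usage_decline_rate=0.85,
        questionnaire_prob=0.35,
        mood_mean=11.0,
    ),
}

DEFAULT_MIXTURE = {
    "responsive_reducer": 0.25,
    "notification_fatigued": 0.25,
    "steady_heavy": 0.15,
    "early_dropout": 0.35,
}


@dataclass(frozen=True)
class DemographicTargets:
    """Marginal targets for the generated cohort (feasibility-cohort shaped)."""

    male_fraction: float = 0.867
    branch_fractions: tuple[float, float, float] = (0.764, 0.113, 0.124)  # army, RAF, navy
    prior_treatment_fraction: float = 0.126
    age_mean: float = 48.4
    age_sd: float = 19.3


@dataclass(frozen=True)
class CohortConfig:
    n_users: int = 200
    archetype_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    seed: int = 0
    weeks: int = 12
    signup_span_days: int = 30
    demographics: DemographicTargets = DemographicTargets()
    #: fraction of registrants who never complete baseline demographics
    frac_missing_demographics: float = 0.037
    #: fraction who did not serve in the armed forces
    frac_non_veteran: float = 0.082
    #: mass of the baseline-units distribution at or below the 14-unit guideline
    baseline_below_threshold_mass: float = 0.16
    #: log-scale sd of multiplicative weekly consumption noise
    noise_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        total = sum(self.archetype_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype mixture weights must sum to 1, got {total}")
        for name in self.archetype_mixture:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype: {name}")


@dataclass(frozen=True)
class UserSeed:
    """Immutable cohort-generation output: who the user is, before any behavior."""

    user_id: str
    demographics: Demographics
    archetype: str
    signup_minute: int
    baseline_weekly_units: float


@dataclass
class UserState:
    """Mutable week-by-week simulation state for one user."""

    seed: UserSeed
    level: float  # latent weekly consumption level
    responsiveness_scale: float = 1.0
    week: int = 0  # last completed week
    attrited: bool = False

    @property
    def archetype(self) -> UserArchetype:
        return ARCHETYPES[self.seed.archetype]


@dataclass(frozen=True)
class WeekResult:
    diary: list[DiaryEntry]
    events: list[AppEvent]
    questionnaire: Optional[QuestionnaireResponse]
    #: input notifications with engagement flags resolved
    notifications: list[NotificationRecord]
    usage_seconds: float
    weekly_units: float


def _draw_baseline_units(rng: np.random.Generator, below_mass: float) -> float:
    """Truncated long-tailed baseline: a lognormal shifted above the
    14-unit guideline, with configurable mass below it so the eligibility
    gate has something to filter."""
    if rng.random() < below_mass:
        return float(rng.uniform(1.0, 14.0))
    return float(min(14.0 + rng.lognormal(mean=2.6, sigma=0.55), 150.0))


def generate_cohort(config: CohortConfig) -> list[UserSeed]:
    """Draw the registrant roster: demographics, archetype, signup, baseline.

    Deterministic given ``config.seed``; demographic margins match the
    configured targets within binomial sampling error.
    """
    rng = np.random.default_rng(config.seed)
    t = config.demographics
    names = sorted(config.archetype_mixture)
    weights = np.array([config.archetype_mixture[n] for n in names])
    branch_p = np.array(t.branch_fractions) / sum(t.branch_fractions)
    branches = list(ServiceBranch)

    seeds: list[UserSeed] = []
    signup_minutes = np.sort(
        rng.integers(0, max(config.signup_span_days, 1) * MINUTES_PER_DAY, size=config.n_users)
    )
    for i in range(config.n_users):
        demo = Demographics(
            age=float(np.clip(rng.normal(t.age_mean, t.age_sd), 18.0, 95.0)),
            gender=Gender.male if rng.random() < t.male_fraction else Gender.female,
            service_branch=branches[int(rng.choice(3, p=branch_p))],
            service_length=float(np.clip(rng.normal(10.0, 7.0), 1.0, 40.0)),
            prior_alcohol_treatment=bool(rng.random() < t.prior_treatment_fraction),
            is_veteran=bool(rng.random() >= config.frac_non_veteran),
            complete=bool(rng.random() >= config.frac_missing_demographics),
        )
        seeds.append(
            UserSeed(
                user_id=f"u{i:05d}",
                demographics=demo,
                archetype=str(rng.choice(names, p=weights)),
                signup_minute=int(signup_minutes[i]),
                baseline_weekly_units=_draw_baseline_units(
                    rng, config.baseline_below_threshold_mass
                ),
            )
        )
    return seeds


def history_from_seed(seed: UserSeed) -> UserHistory:
    return UserHistory(
        user_id=seed.user_id, signup_minute=seed.signup_minute, demographics=seed.demographics
    )


def _spread_units(
    total: float, week_start_day: int, rng: np.random.Generator
) -> list[DiaryEntry]:
    """Distribute a week's units over days, weekend-weighted, dropping
    trace amounts so drink-free days occur."""
    if total <= 0:
        return []
    alpha = np.array([0.6, 0.6, 0.6, 0.6, 0.9, 1.6, 1.6])
    shares = rng.dirichlet(alpha)
    entries = []
    for d in range(DAYS_PER_WEEK):
        units = total * shares[d]
        if units >= 0.5:
            entries.append(DiaryEntry(day=week_start_day + d, units=round(units, 2)))
    return entries


def step_week(
    state: UserState,
    notifications: list[NotificationRecord],
    rng: np.random.Generator,
    noise_sigma: float = 0.15,
    questionnaire: "str | None | tuple[int, int]" = "auto",
) -> WeekResult:
    """Simulate one week for one user.

    Consumption follows ``level <- level * decline * prod(category_effect)``
    over this week's engaged notifications, times multiplicative lognormal
    noise, floored at 0. Each notification is engaged with probability
    ``responsiveness[category] * (1 - fatigue_rate)^k`` where ``k`` counts
    notifications already delivered this week. Attrition is sampled once
    per week; an attrited user logs nothing and never engages.

    ``questionnaire`` controls the weekly self-report: ``"auto"`` draws
    completion internally; ``None`` forces no response; a
    ``(week_index, minute)`` tuple marks a completion pre-drawn by the
    caller (the trial engine does this so reminder scheduling can cease at
    the completion instant).
    """
    if state.attrited:
        raise ValueError("user has attrited; no further weeks to simulate")
    arch = state.archetype
    week = state.week + 1
    week_start_day = state.seed.signup_minute // MINUTES_PER_DAY + DAYS_PER_WEEK * (week - 1)

    # resolve engagement notification-by-notification, fatigue compounding
    resolved: list[NotificationRecord] = []
    engaged_categories: list[NotificationCategory] = []
    for k, nr in enumerate(sorted(notifications, key=lambda n: n.minute)):
        p = arch.responsiveness.get(nr.category, 0.0) * (1.0 - arch.fatigue_rate) ** k
        p *= state.responsiveness_scale
        engaged = bool(rng.random() < p)
        resolved.append(replace(nr, engaged_within_1h=engaged))
        if engaged:
            engaged_categories.append(nr.category)

    # consumption update (week 1 starts at the drawn baseline level)
    if week > 1:
        state.level *= arch.weekly_decline_rate
        for cat in engaged_categories:
            state.level *= arch.category_effect.get(cat, 1.0)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma) if noise_sigma > 0 else 1.0
    weekly = max(state.level * noise, 0.0)

    diary = _spread_units(weekly, week_start_day, rng)

    # app events: sessions with page views; volume tracks engagement level
    usage_scale = arch.usage_decline_rate ** (week - 1) * state.responsiveness_scale
    n_sessions = int(rng.poisson(arch.base_events_per_week * usage_scale / 2.0))
    events: list[AppEvent] = []
    usage_seconds = 0.0
    for _ in range(n_sessions):
        minute = (week_start_day + int(rng.integers(DAYS_PER_WEEK))) * MINUTES_PER_DAY + int(
            rng.integers(8 * 60, 23 * 60)
        )
        events.append(AppEvent(minute=minute, kind=EventKind.session_start))
        for _ in range(1 + int(rng.poisson(1.5))):
            dur = float(rng.gamma(shape=2.0, scale=20.0))
            events.append(
                AppEvent(minute=minute + int(rng.integers(0, 15)), kind=EventKind.page_view, duration_s=dur)
            )
            usage_seconds += dur
        if rng.random() < 0.3:
            events.append(AppEvent(minute=minute + int(rng.integers(0, 15)), kind=EventKind.goal_view))

    # engaged notifications produce an app open within the hour
    for nr in resolved:
        if nr.engaged_within_1h:
            open_min = nr.minute + int(rng.integers(1, 60))
            events.append(AppEvent(minute=open_min, kind=EventKind.session_start))
            events.append(
                AppEvent(minute=open_min + 1, kind=EventKind.message_interaction, duration_s=15.0)
            )
            usage_seconds += 15.0

    def _mood() -> float:
        return float(np.clip(rng.normal(arch.mood_mean, arch.mood_sd), 0.0, 21.0))

    response: Optional[QuestionnaireResponse] = None
    if questionnaire == "auto":
        if rng.random() < arch.questionnaire_prob * max(state.responsiveness_scale, 0.2):
            q_min = week_start_day * MINUTES_PER_DAY + int(
                rng.integers(0, DAYS_PER_WEEK * MINUTES_PER_DAY)
            )
            questionnaire = (week, q_min)
        else:
            questionnaire = None
    if questionnaire is not None:
        _, q_min = questionnaire
        response = QuestionnaireResponse(
            week_index=week, depression=_mood(), anxiety=_mood(), loneliness=_mood()
        )
        events.append(AppEvent(minute=q_min, kind=EventKind.questionnaire_submit))

    # weekly fatigue/attrition bookkeeping
    n_notifs = len(notifications)
    state.responsiveness_scale *= (1.0 - arch.fatigue_rate) ** (0.5 * max(n_notifs - 2, 0))
    state.responsiveness_scale = float(np.clip(state.responsiveness_scale, 0.05, 1.0))
    state.week = week
    if rng.random() < arch.attrition_hazard:
        state.attrited = True

    events.sort(key=lambda e: e.minute)
    return WeekResult(
        diary=diary,
        events=events,
        questionnaire=response,
        notifications=resolved,
        usage_seconds=usage_seconds,
        weekly_units=weekly,
    )
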