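"""Behavioral feature engineering: the rolling 28-day adaptive persona.

The persona is a fixed-length numeric vector summarizing a user's recent
behavior — demographics, app interaction patterns, drink-diary features,
weekly mood self-reports, goal-related engagement, and notification
responsiveness — over a rolling 28-day window ending at the decision
instant. It is the state the reinforcement-learning agent conditions on.

Every non-demographic base metric additionally gets a *change-trend* copy:
its value over the current 7-day week minus its value over the prior week.
The registry (:func:`feature_registry`) fixes the name and order of every
entry, so vector length never varies between users.

Conventions (assumptions, not measurements):

* A day with no diary entry counts as 0 units, i.e. drink-free — the diary
  is the sole consumption source.
* A binge episode is a maximal run of >= 3 consecutive days each strictly
  above 6 units; one episode per maximal run, however long.
* Persona availability requires a minimum number of app events in the
  window (default 3); an unavailable persona means the agent must not be
  consulted and generic messaging is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .records import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    EventKind,
    Gender,
    NotificationCategory,
    ServiceBranch,
    UserHistory,
)

__all__ = [
    "PersonaConfig",
    "PersonaFeatures",
    "FeatureScaler",
    "feature_registry",
    "feature_names",
    "weekly_units",
    "binge_episodes",
    "longest_drink_free_streak",
    "longest_consumption_streak",
    "drink_free_days",
    "build_persona",
]


@dataclass(frozen=True)
class PersonaConfig:
    """Tunable persona parameters.

    ``depression_cutoff`` etc. are score thresholds used for the
    "weeks with depression/anxiety/loneliness" counts; the constructs are
    instrument-agnostic here, so the defaults are placeholders chosen on a
    0-21-ish scale and should be set to match whichever instrument produced
    the scores.
    """

    window_days: int = 28
    min_events_for_availability: int = 3
    binge_units: float = 6.0
    binge_min_days: int = 3
    depression_cutoff: float = 10.0
    anxiety_cutoff: float = 8.0
    loneliness_cutoff: float = 6.0
    latency_cap_h: float = 168.0


DEFAULT_CONFIG = PersonaConfig()

_SERVICE_BRANCH_CODE = {
    ServiceBranch.army: 0.0,
    ServiceBranch.royal_air_force: 1.0,
    ServiceBranch.royal_navy: 2.0,
}


@dataclass(frozen=True)
class PersonaFeatures:
    """The RL state: a fixed-length vector plus an availability flag."""

    as_of: int
    values: np.ndarray
    available: bool

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Pure day-series primitives (shared with the brute-force test oracles)
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean sequence."""
    lengths: list[int] = []
    current = 0
    for flag in mask:
        if flag:
            current += 1
        elif current:
            lengths.append(current)
            current = 0
    if current:
        lengths.append(current)
    return lengths


def _units_series(history: UserHistory, start_day: int, end_day: int) -> np.ndarray:
    """Per-day total units over absolute days [start_day, end_day)."""
    if end_day <= start_day:
        raise ValueError("window must be non-empty")
    series = np.zeros(end_day - start_day)
    for day, units in history.day_units().items():
        if start_day <= day < end_day:
            series[day - start_day] += units
    return series


def weekly_units(history: UserHistory, week_index: int) -> float:
    """Total diary units in study week ``week_index`` (1-based, signup-anchored).

    Week w spans user-relative days ``[7*(w-1), 7*w)``; days without entries
    contribute 0.
    """
    if week_index < 1:
        raise ValueError(f"week_index must be >= 1, got {week_index}")
    start = history.signup_day + DAYS_PER_WEEK * (week_index - 1)
    return float(_units_series(history, start, start + DAYS_PER_WEEK).sum())


def binge_episodes(
    history: UserHistory,
    window: tuple[int, int],
    config: PersonaConfig = DEFAULT_CONFIG,
) -> int:
    """Count binge episodes in absolute-day window ``[start, end)``.

    An episode is a maximal run of consecutive days each strictly above
    ``config.binge_units`` units, of length >= ``config.binge_min_days``.
    """
    series = _units_series(history, *window)
    return sum(1 for r in _runs(series > config.binge_units) if r >= config.binge_min_days)


def longest_drink_free_streak(history: UserHistory, window: tuple[int, int]) -> int:
    """Longest run of days with zero total units in ``[start, end)``."""
    series = _units_series(history, *window)
    return max(_runs(series == 0), default=0)


def longest_consumption_streak(history: UserHistory, window: tuple[int, int]) -> int:
    """Longest run of days with positive total units in ``[start, end)``."""
    series = _units_series(history, *window)
    return max(_runs(series > 0), default=0)


def drink_free_days(history: UserHistory, window: tuple[int, int]) -> int:
    series = _units_series(history, *window)
    return int((series == 0).sum())


# ---------------------------------------------------------------------------
# Windowed feature context
# ---------------------------------------------------------------------------


class _WindowContext:
    """Pre-aggregated per-day arrays for one (history, as_of) pair.

    Feature functions receive this context plus a day-slice ``(lo, hi)``
    relative to the window start, so the same metric can be evaluated over
    the full window, the current week, or the prior week (for trends).
    """

    def __init__(self, history: UserHistory, as_of: int, config: PersonaConfig):
        self.history = history
        self.config = config
        self.as_of = as_of
        n = config.window_days
        self.n_days = n
        self.start_day = as_of // MINUTES_PER_DAY - n
        self.start_minute = self.start_day * MINUTES_PER_DAY

        self.units = _units_series(history, self.start_day, self.start_day + n)

        kinds = list(EventKind)
        self.event_counts = {k: np.zeros(n) for k in kinds}
        self.am_counts = np.zeros(n)
        self.pm_counts = np.zeros(n)
        self.durations: list[list[float]] = [[] for _ in range(n)]
        self.in_window_event_minutes: list[int] = []
        for ev in history.events:
            d = ev.minute // MINUTES_PER_DAY - self.start_day
            if not (0 <= d < n) or ev.minute >= as_of:
                continue
            self.event_counts[ev.kind][d] += 1
            if ev.minute % MINUTES_PER_DAY < 12 * MINUTES_PER_HOUR:
                self.am_counts[d] += 1
            else:
                self.pm_counts[d] += 1
            if ev.duration_s > 0:
                self.durations[d].append(ev.duration_s)
            self.in_window_event_minutes.append(ev.minute)
        self.in_window_event_minutes.sort()

        self.notifications = [
            nr
            for nr in history.notifications
            if self.start_minute <= nr.minute < as_of
        ]
        self.questionnaires = sorted(
            (
                q
                for q in history.questionnaires
                if self._week_in_window(q.week_index)
            ),
            key=lambda q: q.week_index,
        )

    def _week_in_window(self, week_index: int) -> bool:
        wk_start = self.history.signup_day + DAYS_PER_WEEK * (week_index - 1)
        return wk_start + DAYS_PER_WEEK > self.start_day and wk_start < self.start_day + self.n_days

    # -- slice helpers -----------------------------------------------------

    def minute_range(self, lo: int, hi: int) -> tuple[int, int]:
        return (
            (self.start_day + lo) * MINUTES_PER_DAY,
            (self.start_day + hi) * MINUTES_PER_DAY,
        )

    def notifications_in(self, lo: int, hi: int):
        m0, m1 = self.minute_range(lo, hi)
        return [nr for nr in self.notifications if m0 <= nr.minute < m1]

    def questionnaires_in(self, lo: int, hi: int):
        out = []
        for q in self.questionnaires:
            wk_start = self.history.signup_day + DAYS_PER_WEEK * (q.week_index - 1)
            rel = wk_start - self.start_day
            if rel < hi and rel + DAYS_PER_WEEK > lo:
                out.append(q)
        return out

    def n_events_total(self) -> int:
        return len(self.in_window_event_minutes)


FeatureFn = Callable[[_WindowContext, int, int], float]


@dataclass(frozen=True)
class FeatureDef:
    name: str
    domain: str
    fn: FeatureFn
    trend: bool = True  # demographics get trend=False


# ---------------------------------------------------------------------------
# Feature functions
# ---------------------------------------------------------------------------


def _count(kind: EventKind) -> FeatureFn:
    def fn(ctx: _WindowContext, lo: int, hi: int) -> float:
        return float(ctx.event_counts[kind][lo:hi].sum())

    return fn


def _view_duration_mean(ctx: _WindowContext, lo: int, hi: int) -> float:
    vals = [d for day in ctx.durations[lo:hi] for d in day]
    return float(np.mean(vals)) if vals else 0.0


def _view_duration_std(ctx: _WindowContext, lo: int, hi: int) -> float:
    vals = [d for day in ctx.durations[lo:hi] for d in day]
    return float(np.std(vals)) if len(vals) > 1 else 0.0


def _am(ctx, lo, hi):
    return float(ctx.am_counts[lo:hi].sum())


def _pm(ctx, lo, hi):
    return float(ctx.pm_counts[lo:hi].sum())


def _weekly_units_metric(ctx, lo, hi):
    # last 7 days of the slice (the "current week" of that slice)
    return float(ctx.units[max(lo, hi - DAYS_PER_WEEK) : hi].sum())


def _daily_units_mean(ctx, lo, hi):
    return float(ctx.units[lo:hi].mean()) if hi > lo else 0.0


def _binge(ctx, lo, hi):
    runs = _runs(ctx.units[lo:hi] > ctx.config.binge_units)
    return float(sum(1 for r in runs if r >= ctx.config.binge_min_days))


def _weekday_drinking(ctx, lo, hi):
    days = np.arange(ctx.start_day + lo, ctx.start_day + hi)
    return float(((ctx.units[lo:hi] > 0) & (days % 7 < 5)).sum())


def _weekend_drinking(ctx, lo, hi):
    days = np.arange(ctx.start_day + lo, ctx.start_day + hi)
    return float(((ctx.units[lo:hi] > 0) & (days % 7 >= 5)).sum())


def _drink_free(ctx, lo, hi):
    return float((ctx.units[lo:hi] == 0).sum())


def _dfs_streak(ctx, lo, hi):
    return float(max(_runs(ctx.units[lo:hi] == 0), default=0))


def _cons_streak(ctx, lo, hi):
    return float(max(_runs(ctx.units[lo:hi] > 0), default=0))


def _latest_score(attr: str) -> FeatureFn:
    def fn(ctx: _WindowContext, lo: int, hi: int) -> float:
        qs = ctx.questionnaires_in(lo, hi)
        return float(getattr(qs[-1], attr)) if qs else 0.0

    return fn


def _weeks_above(attr: str, cutoff_attr: str) -> FeatureFn:
    def fn(ctx: _WindowContext, lo: int, hi: int) -> float:
        cutoff = getattr(ctx.config, cutoff_attr)
        qs = ctx.questionnaires_in(lo, hi)
        return float(sum(1 for q in qs if getattr(q, attr) >= cutoff))

    return fn


def _n_notifications(category: Optional[NotificationCategory]) -> FeatureFn:
    def fn(ctx: _WindowContext, lo: int, hi: int) -> float:
        recs = ctx.notifications_in(lo, hi)
        if category is None:
            return float(len(recs))
        return float(sum(1 for nr in recs if nr.category == category))

    return fn


def _n_engaged(ctx, lo, hi):
    return float(sum(1 for nr in ctx.notifications_in(lo, hi) if nr.engaged_within_1h))


def _engagement_latency_mean_h(ctx: _WindowContext, lo: int, hi: int) -> float:
    """Mean hours from notification to first subsequent app event, capped.

    Notifications never followed by an event within the cap contribute the
    cap itself (168 h by default).
    """
    cap_min = ctx.config.latency_cap_h * MINUTES_PER_HOUR
    mins = np.asarray(ctx.in_window_event_minutes)
    recs = ctx.notifications_in(lo, hi)
    if not recs:
        return 0.0
    latencies = []
    for nr in recs:
        later = mins[mins >= nr.minute] if mins.size else mins
        gap = float(later[0] - nr.minute) if later.size else cap_min
        latencies.append(min(gap, cap_min))
    return float(np.mean(latencies)) / MINUTES_PER_HOUR


def _goal_notifications(ctx, lo, hi):
    return float(sum(1 for nr in ctx.notifications_in(lo, hi) if nr.bct_tag == "goal_setting"))


def _goal_engagements_1h(ctx: _WindowContext, lo: int, hi: int) -> float:
    """Engagements within 1 h of a goal-setting-tagged notification."""
    mins = np.asarray(ctx.in_window_event_minutes)
    n = 0
    for nr in ctx.notifications_in(lo, hi):
        if nr.bct_tag != "goal_setting":
            continue
        if mins.size and ((mins >= nr.minute) & (mins < nr.minute + 60)).any():
            n += 1
    return float(n)


def _demographic(name: str) -> FeatureFn:
    def fn(ctx: _WindowContext, lo: int, hi: int) -> float:
        d = ctx.history.demographics
        if name == "age":
            return float(d.age)
        if name == "gender_male":
            return 1.0 if d.gender == Gender.male else 0.0
        if name == "service_branch":
            return _SERVICE_BRANCH_CODE[d.service_branch]
        if name == "service_length":
            return float(d.service_length)
        if name == "prior_alcohol_treatment":
            return 1.0 if d.prior_alcohol_treatment else 0.0
        raise KeyError(name)

    return fn


def _base_registry() -> list[FeatureDef]:
    defs: list[FeatureDef] = [
        FeatureDef(n, "demographics", _demographic(n), trend=False)
        for n in ("age", "gender_male", "service_branch", "service_length", "prior_alcohol_treatment")
    ]

    app_metrics: list[tuple[str, FeatureFn]] = [
        ("n_sessions", _count(EventKind.session_start)),
        ("n_page_views", _count(EventKind.page_view)),
        ("view_duration_mean_s", _view_duration_mean),
        ("view_duration_std_s", _view_duration_std),
        ("n_goal_views", _count(EventKind.goal_view)),
        ("n_message_interactions", _count(EventKind.message_interaction)),
        ("n_am_interactions", _am),
        ("n_pm_interactions", _pm),
    ]
    # each app metric at three granularities: last day, last 7 days, full window
    for name, fn in app_metrics:
        for gran, span in (("daily", 1), ("weekly", 7), ("28d", 28)):
            defs.append(
                FeatureDef(
                    f"{name}_{gran}",
                    "app_interactions",
                    _spanned(fn, span),
                    trend=(gran == "weekly"),  # one trend per metric, on the weekly copy
                )
            )

    for name, fn in (
        ("weekly_units", _weekly_units_metric),
        ("daily_units_mean", _daily_units_mean),
        ("binge_episodes", _binge),
        ("weekday_drinking_days", _weekday_drinking),
        ("weekend_drinking_days", _weekend_drinking),
        ("drink_free_days", _drink_free),
        ("longest_drink_free_streak", _dfs_streak),
        ("longest_consumption_streak", _cons_streak),
    ):
        defs.append(FeatureDef(name, "alcohol", fn))

    for name, fn in (
        ("depression_score", _latest_score("depression")),
        ("anxiety_score", _latest_score("anxiety")),
        ("loneliness_score", _latest_score("loneliness")),
        ("weeks_with_depression", _weeks_above("depression", "depression_cutoff")),
        ("weeks_with_anxiety", _weeks_above("anxiety", "anxiety_cutoff")),
        ("weeks_with_loneliness", _weeks_above("loneliness", "loneliness_cutoff")),
    ):
        defs.append(FeatureDef(name, "questionnaire", fn))

    for name, fn in (
        ("n_goal_notifications", _goal_notifications),
        ("goal_engagements_within_1h", _goal_engagements_1h),
    ):
        defs.append(FeatureDef(name, "goal_setting", fn))

    for name, fn in (
        ("n_notifications_sent", _n_notifications(None)),
        ("n_generic_notifications", _n_notifications(NotificationCategory.generic)),
        ("n_personalized_notifications", _n_notifications(NotificationCategory.personalized)),
        ("n_event_notifications", _n_notifications(NotificationCategory.personalized_event)),
        ("n_notification_engagements", _n_engaged),
        ("mean_engagement_latency_h", _engagement_latency_mean_h),
    ):
        defs.append(FeatureDef(name, "notifications", fn))
    return defs


def _spanned(fn: FeatureFn, span: int) -> FeatureFn:
    def wrapped(ctx: _WindowContext, lo: int, hi: int) -> float:
        return fn(ctx, max(lo, hi - span), hi)

    return wrapped


def feature_registry(config: PersonaConfig = DEFAULT_CONFIG) -> list[str]:
    """Ordered feature names of the persona vector, trends included."""
    base = _base_registry()
    names = [d.name for d in base]
    names += [f"trend_{_trend_name(d)}" for d in base if d.trend]
    return names


def _trend_name(d: FeatureDef) -> str:
    return d.name[: -len("_weekly")] if d.name.endswith("_weekly") else d.name


def feature_names(config: PersonaConfig = DEFAULT_CONFIG) -> list[str]:
    return feature_registry(config)


def build_persona(
    history: UserHistory,
    as_of: int,
    config: PersonaConfig = DEFAULT_CONFIG,
) -> PersonaFeatures:
    """Assemble the persona vector over ``[as_of - 28 days, as_of)``.

    ``available`` is False when the user shows fewer than
    ``config.min_events_for_availability`` app events in the window; an
    unavailable persona signals the caller to fall back to generic
    messaging rather than consult the agent. Insufficient data is never an
    error.
    """
    if as_of < history.signup_minute:
        raise ValueError("as_of precedes signup")
    ctx = _WindowContext(history, as_of, config)
    base = _base_registry()
    n = config.window_days
    wk = DAYS_PER_WEEK

    values = [d.fn(ctx, 0, n) for d in base]
    for d in base:
        if d.trend:
            current = d.fn(ctx, n - wk, n)
            prior = d.fn(ctx, n - 2 * wk, n - wk)
            values.append(current - prior)

    available = ctx.n_events_total() >= config.min_events_for_availability
    return PersonaFeatures(as_of=as_of, values=np.asarray(values, dtype=float), available=available)


@dataclass
class FeatureScaler:
    """Per-feature min-max scaling to [0, 1], bounds frozen at training time.

    Out-of-range values seen after the bounds are fixed are clipped, so the
    deployed network never sees inputs outside the training envelope.
    """

    lo: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hi: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def fit(self, vectors: Iterable[np.ndarray]) -> "FeatureScaler":
        mat = np.asarray(list(vectors), dtype=float)
        if mat.size == 0:
            raise ValueError("cannot fit scaler on empty collection")
        self.lo = mat.min(axis=0)
        self.hi = mat.max(axis=0)
        return self

    def transform(self, vec: np.ndarray) -> np.ndarray:
        if self.lo.size == 0:
            return np.asarray(vec, dtype=float)
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((np.asarray(vec, dtype=float) - self.lo) / span, 0.0, 1.0)
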