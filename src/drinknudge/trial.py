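"""The 12-week two-arm feasibility trial engine.

Registrants pass an ordered eligibility cascade (baseline demographics
present, served in the armed forces, baseline weekly consumption strictly
above the 14-unit UK guideline), are allocated to arms by a pre-determined
sequence in signup order, then simulated week by week for 12 weeks. Both
arms receive the same scheduled generic messaging (a weekly generic
message, the weekly questionnaire-due prompt, and up to three 24-hourly
reminders while the questionnaire is uncompleted). The personalized arm
additionally receives personalized and event-triggered messages chosen by
the agent at daily decision points. The analytic sample keeps users with
at least ``retention_min_interactions_per_week`` app interactions in at
least ``retention_min_weeks`` of the 12 weeks, and every stage is
accounted for in a CONSORT-style ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agent as agent_mod
from .persona import DEFAULT_CONFIG, PersonaConfig, build_persona
from .records import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    Gender,
    NotificationCategory,
    NotificationRecord,
    UserHistory,
)
from .simulator import (
    ARCHETYPES,
    CohortConfig,
    UserSeed,
    UserState,
    WeekResult,
    history_from_seed,
    step_week,
)

__all__ = [
    "Arm",
    "TrialConfig",
    "ConsortLedger",
    "TrialResult",
    "apply_eligibility",
    "allocate",
    "retention_filter",
    "schedule_week",
    "run_trial",
]


class Arm(str, Enum):
    control = "control"
    personalized = "personalized"


@dataclass(frozen=True)
class TrialConfig:
    weeks: int = 12
    inclusion_threshold_units: float = 14.0
    retention_min_weeks: int = 6
    retention_min_interactions_per_week: int = 3
    #: repeating allocation pattern over signups: 'C' control, 'P' personalized
    allocation_sequence: str = "CP"
    #: scheduled generic messages per week (both arms)
    generic_per_week: int = 1
    #: daily cap on agent-chosen messages (personalized arm)
    daily_personalized_cap: int = 2
    max_reminders: int = 3
    seed: int = 0
    persona_config: PersonaConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        if self.retention_min_weeks > self.weeks:
            raise ValueError("retention_min_weeks cannot exceed trial weeks")
        if not self.allocation_sequence or set(self.allocation_sequence) - {"C", "P"}:
            raise ValueError("allocation_sequence must be a non-empty string over {'C', 'P'}")


@dataclass
class ConsortLedger:
    """Stage-by-stage participant accounting from registration to analysis."""

    registered: int = 0
    excluded_no_demographics: int = 0
    excluded_not_af: int = 0
    excluded_below_threshold: int = 0
    eligible: int = 0
    allocated: dict[str, int] = field(default_factory=dict)
    excluded_low_usage: dict[str, int] = field(default_factory=dict)
    analyzed: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        excluded = (
            self.excluded_no_demographics
            + self.excluded_not_af
            + self.excluded_below_threshold
        )
        if self.registered - excluded != self.eligible:
            raise AssertionError(
                f"ledger not conserved: {self.registered} - {excluded} != {self.eligible}"
            )
        for arm, n in self.analyzed.items():
            if n > self.allocated.get(arm, 0):
                raise AssertionError(f"analyzed > allocated in arm {arm}")
        for value in (
            self.registered,
            self.excluded_no_demographics,
            self.excluded_not_af,
            self.excluded_below_threshold,
            self.eligible,
            *self.allocated.values(),
            *self.analyzed.values(),
        ):
            if value < 0:
                raise AssertionError("negative ledger count")

    def retained_percentage(self) -> float:
        """Share of registrants reaching the analytic sample, in percent."""
        if self.registered == 0:
            raise ValueError("empty ledger")
        return 100.0 * sum(self.analyzed.values()) / self.registered

    def to_dict(self) -> dict:
        return {
            "registered": self.registered,
            "excluded_no_demographics": self.excluded_no_demographics,
            "excluded_not_af": self.excluded_not_af,
            "excluded_below_threshold": self.excluded_below_threshold,
            "eligible": self.eligible,
            "allocated": dict(self.allocated),
            "excluded_low_usage": dict(self.excluded_low_usage),
            "analyzed": dict(self.analyzed),
        }


def apply_eligibility(
    roster: Sequence[UserSeed], config: TrialConfig = TrialConfig()
) -> tuple[list[UserSeed], ConsortLedger]:
    """Ordered exclusion cascade; each registrant counted at its first failing gate.

    Gates, in order: missing baseline demographics, not having served in
    the armed forces, baseline weekly consumption at or below the
    inclusion threshold (inclusion requires strictly more than 14 units).
    """
    ledger = ConsortLedger(registered=len(roster))
    eligible: list[UserSeed] = []
    for seed in roster:
        if not seed.demographics.complete:
            ledger.excluded_no_demographics += 1
        elif not seed.demographics.is_veteran:
            ledger.excluded_not_af += 1
        elif not seed.baseline_weekly_units > config.inclusion_threshold_units:
            ledger.excluded_below_threshold += 1
        else:
            eligible.append(seed)
    ledger.eligible = len(eligible)
    ledger.validate()
    return eligible, ledger


def allocate(
    eligible: Sequence[UserSeed], config: TrialConfig = TrialConfig()
) -> dict[str, Arm]:
    """Deterministic arm assignment following the configured repeating
    sequence, in signup order."""
    ordered = sorted(eligible, key=lambda s: (s.signup_minute, s.user_id))
    seq = config.allocation_sequence
    mapping = {"C": Arm.control, "P": Arm.personalized}
    return {s.user_id: mapping[seq[i % len(seq)]] for i, s in enumerate(ordered)}


def retention_filter(
    weekly_interactions: Sequence[int], config: TrialConfig = TrialConfig()
) -> bool:
    """Retained iff >= ``retention_min_weeks`` weeks meet the per-week
    interaction minimum. Any app event counts as an interaction."""
    if len(weekly_interactions) != config.weeks:
        raise ValueError(f"expected {config.weeks} weekly counts")
    good = sum(1 for n in weekly_interactions if n >= config.retention_min_interactions_per_week)
    return good >= config.retention_min_weeks


PROMPT_HOUR = 9
GENERIC_HOUR = 18
DECISION_HOUR = 17


def schedule_week(
    history: UserHistory,
    arm: Arm,
    policy: Optional[agent_mod.PolicyState],
    week_index: int,
    rng: np.random.Generator,
    config: TrialConfig = TrialConfig(),
    questionnaire_completed_minute: Optional[int] = None,
) -> list[NotificationRecord]:
    """Build the notification schedule for one user-week.

    Emits the questionnaire-due prompt plus up to ``max_reminders``
    reminders at exactly 24 h spacing, ceasing once the questionnaire is
    completed; the scheduled generic message(s); and, for the personalized
    arm only, agent-chosen personalized/event messages at daily decision
    points subject to the daily cap. The control arm never receives
    personalized or event categories.
    """
    week_start_day = history.signup_day + DAYS_PER_WEEK * (week_index - 1)
    base_minute = week_start_day * MINUTES_PER_DAY
    records: list[NotificationRecord] = []

    prompt_minute = base_minute + PROMPT_HOUR * MINUTES_PER_HOUR
    records.append(
        NotificationRecord(minute=prompt_minute, category=NotificationCategory.questionnaire_prompt)
    )
    for r in range(1, config.max_reminders + 1):
        reminder_minute = prompt_minute + r * 24 * MINUTES_PER_HOUR
        if (
            questionnaire_completed_minute is not None
            and questionnaire_completed_minute <= reminder_minute
        ):
            break
        records.append(
            NotificationRecord(minute=reminder_minute, category=NotificationCategory.reminder)
        )

    for g in range(config.generic_per_week):
        day = 3 + (g % DAYS_PER_WEEK)
        records.append(
            NotificationRecord(
                minute=base_minute + (day % DAYS_PER_WEEK) * MINUTES_PER_DAY + GENERIC_HOUR * MINUTES_PER_HOUR,
                category=NotificationCategory.generic,
                segment_id="gen_selfmon",
                bct_tag="self_monitoring",
            )
        )

    if arm == Arm.personalized and policy is not None:
        for d in range(DAYS_PER_WEEK):
            sent_today = 0
            decision_minute = base_minute + d * MINUTES_PER_DAY + DECISION_HOUR * MINUTES_PER_HOUR
            if decision_minute < history.signup_minute:
                continue
            persona = build_persona(history, decision_minute, config.persona_config)
            recent = [n for n in history.notifications + records if n.minute <= decision_minute]
            category, segment_id = agent_mod.select_action(
                policy, persona, recent=recent, rng=rng, now_minute=decision_minute
            )
            if (
                category
                in (NotificationCategory.personalized, NotificationCategory.personalized_event)
                and segment_id is not None
                and sent_today < config.daily_personalized_cap
            ):
                seg = policy.action_space.segment(segment_id)
                records.append(
                    NotificationRecord(
                        minute=decision_minute,
                        category=category,
                        segment_id=segment_id,
                        bct_tag=seg.bct_tag,
                    )
                )
                sent_today += 1

    records.sort(key=lambda n: n.minute)
    return records


_GENERIC_KINDS = {
    NotificationCategory.generic,
    NotificationCategory.questionnaire_prompt,
    NotificationCategory.reminder,
}


@dataclass
class TrialResult:
    outcomes: pd.DataFrame  # retained users only: the analytic sample
    all_outcomes: pd.DataFrame
    ledger: ConsortLedger
    notification_summary: pd.DataFrame
    histories: dict[str, UserHistory]
    arms: dict[str, Arm]


def run_trial(
    cohort: Sequence[UserSeed],
    policy: Optional[agent_mod.PolicyState],
    config: TrialConfig = TrialConfig(),
    cohort_config: Optional[CohortConfig] = None,
) -> TrialResult:
    """Run the whole trial: eligibility, allocation, 12 simulated weeks per
    user, retention filtering, and CONSORT accounting.

    ``policy`` may be None (no agent traffic; both arms get scheduled
    messaging only). The returned ``outcomes`` table has one row per
    retained user-week with the analysis covariates attached.
    """
    rng = np.random.default_rng(config.seed)
    noise_sigma = cohort_config.noise_sigma if cohort_config is not None else 0.15

    eligible, ledger = apply_eligibility(cohort, config)
    arms = allocate(eligible, config)
    ledger.allocated = {
        arm.value: sum(1 for a in arms.values() if a == arm) for arm in Arm
    }

    rows = []
    histories: dict[str, UserHistory] = {}
    retained_flags: dict[str, bool] = {}
    notif_totals: list[dict] = []

    for seed in sorted(eligible, key=lambda s: (s.signup_minute, s.user_id)):
        arm = arms[seed.user_id]
        user_rng = np.random.default_rng([config.seed, abs(hash(seed.user_id)) % 2**31])
        state = UserState(seed=seed, level=seed.baseline_weekly_units)
        history = history_from_seed(seed)
        weekly_interactions = [0] * config.weeks
        user_rows = []

        for week in range(1, config.weeks + 1):
            if state.attrited:
                break
            # pre-draw questionnaire completion so reminders can cease on it
            arch = state.archetype
            q_drawn = None
            if user_rng.random() < arch.questionnaire_prob * max(state.responsiveness_scale, 0.2):
                week_start_day = seed.signup_minute // MINUTES_PER_DAY + DAYS_PER_WEEK * (week - 1)
                q_minute = week_start_day * MINUTES_PER_DAY + int(
                    user_rng.integers(0, DAYS_PER_WEEK * MINUTES_PER_DAY)
                )
                q_drawn = (week, q_minute)

            notifications = schedule_week(
                history,
                arm,
                policy if arm == Arm.personalized else None,
                week,
                user_rng,
                config,
                questionnaire_completed_minute=q_drawn[1] if q_drawn else None,
            )
            result = step_week(
                state,
                notifications,
                user_rng,
                noise_sigma=noise_sigma,
                questionnaire=q_drawn,
            )
            history.diary.extend(result.diary)
            history.events.extend(result.events)
            history.notifications.extend(result.notifications)
            if result.questionnaire is not None:
                history.questionnaires.append(result.questionnaire)

            # run-time adaptation: segment posteriors keep learning
            if policy is not None and arm == Arm.personalized:
                for nr in result.notifications:
                    if nr.segment_id is not None and nr.category in (
                        NotificationCategory.personalized,
                        NotificationCategory.personalized_event,
                    ):
                        policy = agent_mod.update_posterior(
                            policy, nr.segment_id, nr.engaged_within_1h
                        )

            weekly_interactions[week - 1] = sum(
                1
                for ev in result.events
            )
            counts = {c: 0 for c in NotificationCategory}
            for nr in result.notifications:
                counts[nr.category] += 1
            week_start = seed.signup_minute // MINUTES_PER_DAY + DAYS_PER_WEEK * (week - 1)
            observed_units = sum(
                e.units for e in result.diary if week_start <= e.day < week_start + DAYS_PER_WEEK
            )
            user_rows.append(
                {
                    "user_id": seed.user_id,
                    "arm": arm.value,
                    "week": week,
                    "units": observed_units,
                    "usage_seconds": result.usage_seconds,
                    "n_generic": sum(counts[c] for c in _GENERIC_KINDS),
                    "n_personalized": counts[NotificationCategory.personalized],
                    "n_event": counts[NotificationCategory.personalized_event],
                    "age": seed.demographics.age,
                    "gender": seed.demographics.gender.value,
                    "prior_treatment": int(seed.demographics.prior_alcohol_treatment),
                }
            )

        if policy is not None and arm == Arm.personalized:
            policy = agent_mod.decay_epsilon(policy)

        histories[seed.user_id] = history
        retained = retention_filter(weekly_interactions, config)
        retained_flags[seed.user_id] = retained
        rows.extend(user_rows)
        notif_totals.append(
            {
                "user_id": seed.user_id,
                "arm": arm.value,
                "retained": retained,
                "generic": sum(r["n_generic"] for r in user_rows),
                "personalized": sum(r["n_personalized"] for r in user_rows),
                "personalized_event": sum(r["n_event"] for r in user_rows),
            }
        )

    all_outcomes = pd.DataFrame(rows)
    if not all_outcomes.empty:
        outcomes = all_outcomes[all_outcomes["user_id"].map(retained_flags)].reset_index(
            drop=True
        )
    else:
        outcomes = all_outcomes

    for arm in Arm:
        n_alloc = ledger.allocated[arm.value]
        n_ret = sum(
            1 for uid, keep in retained_flags.items() if keep and arms[uid] == arm
        )
        ledger.analyzed[arm.value] = n_ret
        ledger.excluded_low_usage[arm.value] = n_alloc - n_ret
    ledger.validate()

    notif_df = pd.DataFrame(notif_totals)
    summary = _notification_summary(notif_df)
    return TrialResult(
        outcomes=outcomes,
        all_outcomes=all_outcomes,
        ledger=ledger,
        notification_summary=summary,
        histories=histories,
        arms=arms,
    )


def _notification_summary(notif_df: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) notifications per category per arm, retained users only.

    Control-arm personalized/event cells are absent (NaN), never zero."""
    rows = []
    if notif_df.empty:
        return pd.DataFrame(columns=["arm", "category", "mean", "sd"])
    retained = notif_df[notif_df["retained"]]
    for arm_value, group in retained.groupby("arm"):
        total = group["generic"] + group["personalized"] + group["personalized_event"]
        for cat, series in (
            ("generic", group["generic"]),
            ("personalized", group["personalized"]),
            ("personalized_event", group["personalized_event"]),
            ("total", total),
        ):
            absent = arm_value == Arm.control.value and cat in (
                "personalized",
                "personalized_event",
            )
            rows.append(
                {
                    "arm": arm_value,
                    "category": cat,
                    "mean": np.nan if absent else float(series.mean()),
                    "sd": np.nan
                    if absent or len(series) < 2
                    else float(series.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
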