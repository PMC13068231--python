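"""Eligibility cascade, allocation, retention, scheduling, and the full trial."""

from dataclasses import replace

import numpy as np
import pytest

from drinknudge.agent import AgentHyperparams, PolicyState
from drinknudge.persona import feature_registry
from drinknudge.records import (
    MINUTES_PER_DAY,
    NotificationCategory,
)
from drinknudge.simulator import CohortConfig, generate_cohort, history_from_seed
from drinknudge.trial import (
    Arm,
    TrialConfig,
    allocate,
    apply_eligibility,
    retention_filter,
    run_trial,
    schedule_week,
)

from conftest import make_demographics

CONFIG = TrialConfig()


def make_seed(i, units=30.0, complete=True, veteran=True, signup_minute=None):
    from drinknudge.simulator import UserSeed

    return UserSeed(
        user_id=f"u{i:04d}",
        demographics=make_demographics(complete=complete, is_veteran=veteran),
        archetype="steady_heavy",
        signup_minute=i * 60 if signup_minute is None else signup_minute,
        baseline_weekly_units=units,
    )


class TestEligibility:
    def test_hand_traced_cascade(self):
        roster = (
            [make_seed(i, complete=False) for i in range(2)]
            + [make_seed(2, veteran=False)]
            + [make_seed(i, units=14.0) for i in range(3, 6)]
            + [make_seed(i, units=30.0) for i in range(6, 10)]
        )
        eligible, ledger = apply_eligibility(roster, CONFIG)
        assert len(eligible) == 4
        assert ledger.excluded_no_demographics == 2
        assert ledger.excluded_not_af == 1
        assert ledger.excluded_below_threshold == 3
        assert ledger.eligible == 4

    def test_exactly_14_units_excluded(self):
        """Inclusion requires strictly more than 14 units per week."""
        _, ledger = apply_eligibility([make_seed(0, units=14.0)], CONFIG)
        assert ledger.excluded_below_threshold == 1
        eligible, _ = apply_eligibility([make_seed(0, units=14.01)], CONFIG)
        assert len(eligible) == 1

    def test_first_failing_gate_wins(self):
        """A record failing several gates is counted once, at the first."""
        seed = make_seed(0, units=5.0, complete=False, veteran=False)
        _, ledger = apply_eligibility([seed], CONFIG)
        assert ledger.excluded_no_demographics == 1
        assert ledger.excluded_not_af == 0
        assert ledger.excluded_below_threshold == 0

    def test_printed_stage_sizes_reproduce_eligible_count(self):
        """A roster with the reported funnel composition (2,871 registered;
        107 missing demographics, 235 non-veteran, 409 at or below 14
        units, disjoint) yields the reported 2,120 eligible."""
        roster = (
            [make_seed(i, complete=False) for i in range(107)]
            + [make_seed(107 + i, veteran=False) for i in range(235)]
            + [make_seed(342 + i, units=10.0) for i in range(409)]
            + [make_seed(751 + i, units=25.0) for i in range(2120)]
        )
        assert len(roster) == 2871
        eligible, ledger = apply_eligibility(roster, CONFIG)
        assert ledger.eligible == len(eligible) == 2120
        ledger.analyzed = {"control": 385, "personalized": 343}
        ledger.allocated = {"control": 1218, "personalized": 902}
        assert round(ledger.retained_percentage(), 1) == 25.4


class TestAllocation:
    def test_alternation_control_first(self):
        seeds = [make_seed(i) for i in range(4)]
        arms = allocate(seeds, TrialConfig(allocation_sequence="CP"))
        assert [arms[s.user_id] for s in seeds] == [
            Arm.control,
            Arm.personalized,
            Arm.control,
            Arm.personalized,
        ]

    def test_odd_count_sizes(self):
        seeds = [make_seed(i) for i in range(5)]
        arms = allocate(seeds, TrialConfig(allocation_sequence="CP"))
        sizes = {a: list(arms.values()).count(a) for a in Arm}
        assert sizes == {Arm.control: 3, Arm.personalized: 2}

    def test_custom_repeating_sequence(self):
        seeds = [make_seed(i) for i in range(6)]
        arms = allocate(seeds, TrialConfig(allocation_sequence="PPC"))
        sizes = {a: list(arms.values()).count(a) for a in Arm}
        assert sizes == {Arm.personalized: 4, Arm.control: 2}

    def test_order_follows_signup_not_input(self):
        seeds = [make_seed(i) for i in range(4)][::-1]
        arms = allocate(seeds, TrialConfig(allocation_sequence="CP"))
        ordered = sorted(seeds, key=lambda s: s.signup_minute)
        assert arms[ordered[0].user_id] == Arm.control


class TestRetention:
    def test_boundary_exactly_meets_criterion(self):
        counts = [3] * 6 + [0] * 6
        assert retention_filter(counts, CONFIG) is True

    def test_two_per_week_never_qualifies(self):
        assert retention_filter([2] * 12, CONFIG) is False

    def test_five_qualifying_weeks_insufficient(self):
        assert retention_filter([3] * 5 + [0] * 7, CONFIG) is False

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            retention_filter([3] * 10, CONFIG)


class TestScheduleWeek:
    def history(self):
        return history_from_seed(make_seed(0, signup_minute=0))

    def test_uncompleted_questionnaire_prompts_and_three_reminders(self, rng):
        records = schedule_week(self.history(), Arm.control, None, 1, rng, CONFIG)
        prompts = [r for r in records if r.category == NotificationCategory.questionnaire_prompt]
        reminders = [r for r in records if r.category == NotificationCategory.reminder]
        assert len(prompts) == 1 and len(reminders) == 3
        gaps = np.diff([prompts[0].minute] + [r.minute for r in reminders])
        assert all(g == 24 * 60 for g in gaps)

    def test_completion_before_first_reminder_silences_reminders(self, rng):
        records = schedule_week(
            self.history(), Arm.control, None, 1, rng, CONFIG,
            questionnaire_completed_minute=10 * 60,
        )
        assert sum(r.category == NotificationCategory.reminder for r in records) == 0

    def test_completion_mid_window_truncates_reminders(self, rng):
        # completed 30 h after week start: prompt (9 h) + first reminder (33 h)
        records = schedule_week(
            self.history(), Arm.control, None, 1, rng, CONFIG,
            questionnaire_completed_minute=40 * 60,
        )
        assert sum(r.category == NotificationCategory.reminder for r in records) == 1

    def test_control_arm_gets_no_agent_messages(self, rng):
        records = schedule_week(self.history(), Arm.control, None, 3, rng, CONFIG)
        cats = {r.category for r in records}
        assert NotificationCategory.personalized not in cats
        assert NotificationCategory.personalized_event not in cats


def small_trial(policy=None, n_users=80, seed=5):
    cc = CohortConfig(n_users=n_users, seed=seed)
    return run_trial(generate_cohort(cc), policy, TrialConfig(seed=seed), cohort_config=cc)


def trained_like_policy(seed=5):
    policy = PolicyState.fresh(
        n_features=len(feature_registry()), hyperparams=AgentHyperparams(), seed=seed
    )
    policy.epsilon = 0.1
    return policy


class TestRunTrial:
    def test_ledger_conserved_and_nonnegative(self):
        result = small_trial()
        result.ledger.validate()
        led = result.ledger.to_dict()
        assert led["registered"] == 80
        assert sum(led["allocated"].values()) == led["eligible"]

    def test_no_policy_means_no_agent_traffic(self):
        result = small_trial(policy=None)
        assert result.all_outcomes["n_personalized"].sum() == 0
        assert result.all_outcomes["n_event"].sum() == 0

    def test_control_arm_never_personalized(self):
        """Full-trace scan: no control-arm record carries a personalized or
        event category, even with an active policy."""
        result = small_trial(policy=trained_like_policy())
        for uid, arm in result.arms.items():
            if arm != Arm.control:
                continue
            for nr in result.histories[uid].notifications:
                assert nr.category not in (
                    NotificationCategory.personalized,
                    NotificationCategory.personalized_event,
                )

    def test_personalized_arm_receives_more_notifications(self):
        """Direction only: with an agent that sends messages, the
        personalized arm's mean total notification count exceeds control."""
        result = small_trial(policy=trained_like_policy(), n_users=120)
        s = result.notification_summary.set_index(["arm", "category"])["mean"]
        assert (
            s[(Arm.personalized.value, "total")] > s[(Arm.control.value, "total")]
        )

    def test_reminder_schedule_invariant(self):
        """Per questionnaire week: one prompt, at most 3 reminders, exactly
        24 h apart, and reminders only while uncompleted."""
        result = small_trial(policy=trained_like_policy())
        for uid, h in result.histories.items():
            by_week = {}
            for nr in h.notifications:
                week = (nr.minute // MINUTES_PER_DAY - h.signup_day) // 7
                by_week.setdefault(week, []).append(nr)
            for week, notes in by_week.items():
                prompts = [n for n in notes if n.category == NotificationCategory.questionnaire_prompt]
                reminders = sorted(
                    (n for n in notes if n.category == NotificationCategory.reminder),
                    key=lambda n: n.minute,
                )
                assert len(prompts) == 1
                assert len(reminders) <= 3
                times = [prompts[0].minute] + [r.minute for r in reminders]
                assert all(b - a == 24 * 60 for a, b in zip(times, times[1:]))

    def test_outcomes_restricted_to_retained(self):
        result = small_trial()
        analyzed = sum(result.ledger.analyzed.values())
        assert result.outcomes["user_id"].nunique() == analyzed

    def test_notification_summary_control_cells_absent(self):
        result = small_trial(policy=trained_like_policy())
        s = result.notification_summary.set_index(["arm", "category"])["mean"]
        assert np.isnan(s[(Arm.control.value, "personalized")])
        assert np.isnan(s[(Arm.control.value, "personalized_event")])
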