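"""The eligibility cascade on the published funnel composition.

Builds a roster of 2,871 registrants whose exclusion-stage sizes match
the reported recruitment funnel (107 without baseline demographics, 235
who had not served in the armed forces, 409 at or below 14 units/week)
and verifies the cascade reproduces the reported 2,120 eligible and the
25.4% retained share given the reported analyzed arm sizes.
"""

from drinknudge.records import Demographics, Gender, ServiceBranch
from drinknudge.simulator import UserSeed
from drinknudge.trial import TrialConfig, apply_eligibility


def seed(i, units, complete=True, veteran=True):
    return UserSeed(
        user_id=f"r{i:05d}",
        demographics=Demographics(
            age=48.0, gender=Gender.male, service_branch=ServiceBranch.army,
            service_length=10.0, prior_alcohol_treatment=False,
            is_veteran=veteran, complete=complete,
        ),
        archetype="steady_heavy",
        signup_minute=i,
        baseline_weekly_units=units,
    )


roster = (
    [seed(i, 30.0, complete=False) for i in range(107)]
    + [seed(107 + i, 30.0, veteran=False) for i in range(235)]
    + [seed(342 + i, 9.0) for i in range(409)]
    + [seed(751 + i, 28.0) for i in range(2120)]
)

eligible, ledger = apply_eligibility(roster, TrialConfig())
print(f"registered:                  {ledger.registered}")
print(f"  no baseline demographics:  -{ledger.excluded_no_demographics}")
print(f"  not armed forces:          -{ledger.excluded_not_af}")
print(f"  at or below 14 units/week: -{ledger.excluded_below_threshold}")
print(f"eligible:                    {ledger.eligible}")

ledger.allocated = {"control": 1218, "personalized": 902}
ledger.analyzed = {"control": 385, "personalized": 343}
print(f"analyzed (385 + 343):        {sum(ledger.analyzed.values())}")
print(f"retained percentage:         {ledger.retained_percentage():.1f}%")
print(
    "\nGates apply in order, so a registrant failing several is counted"
    "\nonce at the first; inclusion requires strictly more than 14 units."
)
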