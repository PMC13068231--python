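"""Run the full 12-week two-arm trial on a simulated cohort and analyze it.

Generates registrants, applies the eligibility cascade (demographics
present, veteran, baseline strictly above 14 UK units/week), allocates by
alternation in signup order, simulates 12 weeks per user, filters to the
retained analytic sample (3+ interactions/week in 6+ weeks), then fits
the random-intercept mixed model and prints per-week estimated marginal
means with the personalized-minus-control differences.
"""

import warnings

from drinknudge.analysis import descriptives, estimated_marginal_means, fit_outcome_model
from drinknudge.simulator import CohortConfig, generate_cohort
from drinknudge.trial import TrialConfig, run_trial

cohort_config = CohortConfig(n_users=400, seed=31)
result = run_trial(
    generate_cohort(cohort_config), policy=None, config=TrialConfig(seed=31),
    cohort_config=cohort_config,
)

ledger = result.ledger.to_dict()
print("participant flow:", ledger)
print(f"retained: {result.ledger.retained_percentage():.1f}% of registrants\n")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_outcome_model(result.outcomes, outcome="units")
    emm = estimated_marginal_means(fit, result.outcomes, outcome="units")

wide = emm.means.pivot(index="week", columns="arm", values="emm").round(1)
table = wide.join(emm.differences.set_index("week")[["difference", "p_value"]].round(3))
print("estimated marginal mean weekly units by arm:")
print(table.to_string())

print("\nnotification volumes (mean per retained user):")
print(descriptives(result)["notifications"].round(1).to_string(index=False))
print(
    "\nBoth arms decline over 12 weeks (the simulator's built-in trend);"
    "\nwith no policy supplied the arms differ only by sampling noise, so"
    "\ndifferences hover near 0 and most p-values are non-significant."
)
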