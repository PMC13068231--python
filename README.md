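# drinknudge

Reinforcement-learning personalization of behavior-change push
notifications for an alcohol-reduction app, aimed at heavy-drinking UK
armed-forces veterans — together with everything needed to train, trial,
and analyze the method without access to real participant data: a
synthetic veteran-cohort simulator, a 12-week two-arm trial engine with
CONSORT-style accounting, and linear mixed-model analysis of the trial
outcomes.

It is a library first (import `drinknudge`, see `examples/`) with a thin
CLI (`drinknudge simulate-cohort | train | run-trial | analyze | report`)
for running the pipeline from a shell.

## The method

**State.** Each user's behavior over a rolling 28-day window is summarized
into an 81-dimensional *adaptive persona*: demographics; app-interaction
counts and view durations at daily/weekly/28-day granularity; drink-diary
features (weekly units, binge episodes — runs of ≥ 3 consecutive days
each above 6 UK units — drink-free days, longest drink-free and drinking
streaks, weekday/weekend patterns); weekly depression/anxiety/loneliness
scores; goal-related engagement; notification counts and
notification-to-engagement latency (capped at 168 h); plus a change-trend
copy of every non-demographic feature (current week minus prior week).
Users with fewer than 3 app events in the window get no persona and fall
back to generic messaging.

**Policy.** A deep Q-network Q(s, a) over min-max-scaled personas scores
four actions: *no message*, *generic*, *personalized*, *personalized
(event)*. Exploration is ε-greedy with multiplicative decay
(ε ← max(ε_min, ε·d), d ∈ [0.95, 0.99]). Within the chosen category, a
Beta-Bernoulli Thompson draw per message segment picks which
BCT-tagged segment to send, and declarative co-occurrence rules keep
clashing message themes from appearing within a configurable window.
Training is standard DQN — replay buffer, lagged target network,
y = r + γ·max_a′ Q̄(s′, a′), γ ∈ [0.7, 0.95] — with user-level k-fold
cross-validation, early stopping on validation-reward plateau, and
Gaussian-process hyperparameter search over the allowed ranges.

**Reward.** Behavioral triggers map into three bands: app engagement
within 1 h of a message → +1..+10; weekly consumption reduction or more
drink-free days → +10..+20; disengagement after ≥ 3 consecutive ignored
notifications, increased consumption, or a shifted drinking pattern →
−5..−10. Within a band, components ramp linearly in trigger magnitude and
saturate.

**Trial & analysis.** Registrants pass an ordered eligibility cascade
(baseline demographics present → served in the armed forces → baseline
strictly above 14 units/week), are allocated by a pre-determined sequence
in signup order, and are simulated for 12 weeks; the analytic sample
keeps users with ≥ 3 app interactions/week in ≥ 6 of 12 weeks. Outcomes
are analyzed with a linear mixed model with random participant
intercepts, fixed effects arm × categorical week plus age, gender and
prior alcohol treatment (REML), and per-week estimated marginal means
with Wald 95% CIs and between-arm differences (unadjusted and
Holm-adjusted p-values).

## Worked example

`python examples/consort_funnel.py` runs the eligibility cascade on a
roster whose stage sizes match the published recruitment funnel:

```
registered:                  2871
  no baseline demographics:  -107
  not armed forces:          -235
  at or below 14 units/week: -409
eligible:                    2120
analyzed (385 + 343):        728
retained percentage:         25.4%
```

Each gate counts a registrant at its first failure; 2,120 of 2,871
registrants survive the cascade, and with the analyzed arm sizes of 385
and 343 the retained share is 25.4% of registrants.

`python examples/reward_signal.py` scores one notification — the user
opens the app 25 minutes after a personalized message, and their diary
shows the week down 6 units on the week before:

```
trigger: engaged_within_window        magnitude 1.0
trigger: weekly_units_decreased       magnitude 6.0

total reward: 22.80
```

The engagement trigger lands at 2.8 inside its +1..+10 band and the
6-unit reduction saturates the +10..+20 band at 20, summing to 22.8.

Other examples: `build_persona.py` (feature vector for a hand-crafted
month of history), `train_policy.py` (training shifts the greedy policy
onto a category rigged to dominate rewards), and
`run_trial_and_analyze.py` (full simulated trial plus mixed-model EMM
table).

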