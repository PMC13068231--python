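# Methods

This note documents the models and procedures the package implements, the
assumptions baked into them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Time and calendar conventions

Simulated time is an integer minute offset from a fixed epoch
(2020-01-06 00:00 UTC, a Monday). A day is `minute // 1440`; day-of-week
is `day % 7`, so days 5–6 of each block are the weekend. Study weeks are
7-day blocks anchored at each user's signup day (signup day = day 0),
half-open `[7(w−1), 7w)` for week `w ≥ 1`. Every piece of day arithmetic
in the package uses this one convention. AM/PM interaction counts split
at 12:00 of the simulated clock.

## The adaptive persona

The persona is an 81-entry vector computed over `[as_of − 28 d, as_of)`.
The registry (`drinknudge.persona.feature_registry`) fixes name and order;
51 base features plus 30 change-trend features. Trends are defined as the
metric evaluated over the current 7-day week minus the prior week; app
metrics that appear at three granularities (daily / weekly / 28-day) get
one trend each, computed on the weekly copy, to avoid triplicated
entries.

Assumptions worth knowing:

* **A missing diary day is 0 units** (drink-free). The in-app diary is
  the sole consumption source, so an unlogged day cannot be
  distinguished from an abstinent one; we choose the optimistic reading
  and flag it here.
* **Binge episode** = one count per *maximal* run of ≥ 3 consecutive
  days each strictly above 6 units (a 5-day run is one episode, not
  three overlapping windows). The rule lives in one function so an
  overlapping-window variant is a local change.
* **Availability** requires ≥ 3 app events in the 28-day window
  (configurable). This mirrors the retention criterion's granularity of
  3 interactions/week; an unavailable persona routes the user to generic
  messaging and the agent is never consulted.
* **Questionnaire constructs are instrument-agnostic.** Depression,
  anxiety and loneliness arrive as plain numbers; the
  "weeks with …" counts use configurable cut-offs (defaults 10/8/6 on a
  0–21-style scale) that are placeholders, not clinical thresholds.
* **Goal-setting features** are limited to the two signals the event
  model carries — goal-progress views and engagements within 1 h of a
  goal-tagged notification. Richer goal lifecycle metrics (set / missed /
  achieved, time-to-goal) would need event kinds the closed event
  enumeration deliberately does not include.
* **Latency** from notification to the next app event is clipped to
  [0, 168] h; notifications never followed by an event contribute the cap.

Feature scaling for the RL state is per-feature min–max to [0, 1] with
bounds frozen at training time (from an agent-free warmup simulation) and
stored in the policy checkpoint; out-of-range values at run time are
clipped.

## Reward

Three bands: engagement `[+1, +10]`, consumption-reduction `[+10, +20]`,
penalty `[−10, −5]`. A component is placed inside its band by a linear
ramp in the trigger magnitude (units reduced, drink-free days gained,
consecutive ignored notifications), saturating at the band's far end at
`ramp_scale` (default 5). Multiple simultaneous triggers *add*; the
containment property (no component ever escapes its band) is
property-tested. Trigger extraction:

* engagement — any app event within 1 h of the notification;
* weekly change — the signup-anchored week containing the notification
  versus the week before it;
* disengagement — the most recent 3 notifications (configurable) all
  unengaged;
* drinking-pattern change — a weekday↔weekend consumption-share shift
  above 25% (configurable); this trigger is named but not defined by the
  deployed rule set, so the operationalization is ours.

Rewards are aggregated per decision step (one notification opportunity
per user-day), not per calendar day.

## The agent

Action space: `no_message`, `generic`, `personalized`,
`personalized_event`, in that fixed order. Including `no_message` makes
notification dose learnable — fatigue penalties are only avoidable if
restraint is an action.

The Q-network is a fully-connected ReLU network (default 2 × 64) in plain
numpy, trained by SGD on squared TD error against a lagged target network
(sync every 100 updates), with gradients rescaled to a global norm of at
most 10 — without clipping, early training on large rewards can diverge.
Allowed hyperparameter ranges are enforced at construction: learning rate
[0.001, 0.1], discount [0.7, 0.95], exploration decay [0.95, 0.99].

Thompson sampling composes hierarchically: the network (plus ε-greedy)
picks the *category*; a Beta(α, β) posterior per message *segment*
(conjugate ±1 updates on engagement) picks the segment within it by
posterior draw. This keeps segment-level adaptation running after the
network is frozen. Co-occurrence rules are declarative (tag-pair +
window, default 24 h) and prune candidate segments against recently sent
tags before selection; if nothing survives, no message is sent.

Deployment is frozen: after training only ε decay, posterior updates and
persona refresh continue. All randomness flows from one seeded generator
per run; the checkpoint (single JSON archive) carries network parameters,
scaler bounds, posteriors, ε, rules and hyperparameters.

## The simulator

Four archetypes span the engagement spectrum — `responsive_reducer`,
`notification_fatigued`, `steady_heavy`, `early_dropout` — mixed by
default 0.25 / 0.25 / 0.15 / 0.35. Weekly dynamics per user:

* consumption level `L_w = L_{w−1} · decline · Π effect(c)` over engaged
  notification categories, times multiplicative lognormal noise
  (σ = 0.15), floored at 0; week 1 starts at the drawn baseline;
* engagement of the k-th notification in a week is Bernoulli with
  probability `responsiveness(category) · (1 − fatigue)^k · scale`,
  where `scale` also decays across weeks with notification volume;
* attrition is sampled once per week; an attrited user logs nothing;
* app events (sessions with page views, occasional goal views) scale with
  the archetype's usage level and its weekly usage decline; engaged
  notifications always produce an app open within the hour;
* weekly units are spread over days by a weekend-weighted Dirichlet with
  trace amounts dropped, so drink-free days occur.

Baselines are drawn from a shifted lognormal above the 14-unit guideline
with a configurable 16% mass below it, so the eligibility gate has
something to filter; demographic margins default to the feasibility
cohort's shape (86.7% male, army/RAF/navy ≈ 76/11/12, 12.6% prior
treatment, mean age 48.4). Under the default configuration the simulated
retained fraction lands in the 15–40% range; this is a realism smoke
test, not a fitted quantity.

What the generator does **not** emulate: within-day drinking structure,
seasonal or weekday effects beyond the weekend weighting, correlated
mood–drinking dynamics, self-report biases, or any claim of veteran-
population realism. Tests passing against it show the *pipeline* behaves
correctly under plausible shapes, not that the intervention works on real
users.

## Training

One episode = one simulated user over 12 weeks with one decision per
user-day. Cross-validation folds cut across users (transitions within a
user are dependent); each fold trains on 80% of users and evaluates mean
greedy episodic reward on the held-out 20%. Early stopping ends a fold
when validation reward has not improved by more than 1% (relative) for 3
consecutive evaluations — and never before that many evaluations have
happened. The returned policy is the best-validation one across folds.

Hyperparameter search is sequential model-based: 5 random starts, then a
Matérn-kernel Gaussian-process surrogate proposing by expected
improvement over random candidate pools; learning rate is searched on a
log scale; every proposal is asserted inside the allowed ranges.

## The trial engine

Eligibility gates apply **in order** (demographics → armed-forces service
→ baseline strictly > 14 units/week), each registrant counted at its
first failure — the only convention under which stage-size accounting is
reproducible. Allocation follows a repeating configurable sequence
(default strict alternation `CP`) over signup order; the observed
cohort's unbalanced arm sizes show the deployed sequence was not
balanced, which is why the sequence is configurable rather than
hard-coded.

Both arms receive the scheduled stream: one generic message per week, a
questionnaire-due prompt (09:00, week start) and up to 3 reminders at
exactly 24 h spacing that cease at questionnaire completion. The
personalized arm additionally consults the agent once per day (daily cap
2) and receives its personalized/event choices; an agent choice of
`generic` or `no_message` sends nothing extra, keeping generic volume
comparable across arms. Retention = ≥ 3 app events/week in ≥ 6 of 12
weeks; any event kind counts as an interaction. The CONSORT ledger's
conservation (registered = Σ exclusions + eligible; analyzed ≤ allocated)
is asserted on every run, not sampled.

## Analysis

Both outcomes (weekly units; weekly app-usage seconds) share one code
path: `outcome ~ arm * C(week) + age + gender + prior_treatment` with a
random participant intercept, fit by REML (statsmodels MixedLM).
Convergence warnings are surfaced, never swallowed. EMMs are computed by
averaging the design row over the observed covariate distribution with
arm and week set — for a linear model this is identical to evaluation at
covariate means — with Wald 95% intervals from the fixed-effect
covariance (normal approximation; the df method is recorded in the output
metadata). Per-week between-arm differences are reported with both
unadjusted and Holm-adjusted p-values: the headline published comparisons
appear consistent with unadjusted per-week Wald tests, so both columns
are emitted and the choice is left to the reader. Missing user-weeks stay
missing; mixed models tolerate unbalanced panels and no imputation is
attempted.

`synthesize_outcome_table` draws panels directly from this model family
(cell means + random intercept + i.i.d. noise). It exists for calibration
experiments — null CI coverage and injected-effect recovery — where the
model must be correctly specified by construction; it is not a behavioral
simulator.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 150–400 users,
training runs of 2 folds × 30 episodes on 200-user cohorts, and 50
replicates per mixed-model calibration experiment (400 users for effect
recovery, 150 for null coverage) — sizes chosen so the full pipeline
exercises every code path in minutes on one CPU while keeping Monte Carlo
error well inside the asserted margins. Ties in greedy action selection
resolve to the lowest category index (numpy argmax); degenerate inputs
(empty event sets, single-user cells, all-excluded candidate sets) return
empty/absent values rather than raising, except where a precondition is
violated outright.

## Known limitations

* Total notification volumes in simulated trials exceed a deployed app's
  (reminder streams dominate when questionnaire completion is low);
  directional arm comparisons are meaningful, absolute volumes are not.
* The co-occurrence rule set ships as configurable placeholders; the
  deployed rule list is not public.
* Message segments are identifiers with BCT tags — no text, no language
  generation.
* The real cohort's outcome tables derive from participant data that is
  not public; nothing here attempts to reproduce those cell values, only
  the procedures that would produce them.
* Post-allocation exclusion accounting in the published funnel does not
  reconcile arithmetically with the allocated and analyzed counts; the
  ledger here enforces conservation instead of reproducing that
  discrepancy.
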