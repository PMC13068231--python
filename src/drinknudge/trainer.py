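"""Offline DQN training against the simulator.

Training is episodic: one episode is one simulated user followed over the
configured number of weeks, with one notification opportunity per
user-day. Cross-validation folds are cut across *users* (transitions
within a user are dependent, so record-level folding would leak), with
the standard 80/20 train/validation split per fold. Validation reward is
the mean greedy episodic reward on the held-out users; early stopping
ends a fold once validation reward stops improving by more than a
relative plateau tolerance for a patience window.

Hyperparameter search (:func:`tune`) is sequential model-based: a
Gaussian-process surrogate with expected-improvement acquisition over the
allowed ranges (learning rate 0.001–0.1, discount 0.7–0.95, exploration
decay 0.95–0.99), falling back to pure random search for tiny budgets.
Every proposal is asserted to lie inside the search space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from . import agent as agent_mod
from .agent import (
    DISCOUNT_RANGE,
    EPSILON_DECAY_RANGE,
    LEARNING_RATE_RANGE,
    AgentHyperparams,
    PolicyState,
    Transition,
)
from .persona import PersonaConfig, build_persona, feature_registry
from .records import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    NotificationCategory,
    NotificationRecord,
)
from .reward import RewardSpec, compute_reward, derive_reward_events
from .simulator import UserSeed, UserState, history_from_seed, step_week

__all__ = [
    "TrainingConfig",
    "TrainingDiagnostics",
    "RewardFn",
    "default_reward_fn",
    "make_rigged_reward",
    "fit_scaler",
    "run_episode",
    "train",
    "tune",
]

DECISION_HOUR = 17

#: maps (history-after-week, notification-or-None, spec) to a scalar reward
RewardFn = Callable[[object, Optional[NotificationRecord], RewardSpec], float]


def default_reward_fn(history, notification, spec: RewardSpec) -> float:
    """The rule-based reward: band-mapped behavioral triggers."""
    if notification is None:
        return 0.0
    return compute_reward(derive_reward_events(history, notification, spec), spec)


def make_rigged_reward(
    dominant: NotificationCategory, factor: float = 10.0, base: float = 1.0
) -> RewardFn:
    """A diagnostic reward where one category dominates all others ``factor``-fold.

    Used to verify the learning loop end to end: a correct agent must
    discover and exploit the dominant category.
    """

    def fn(history, notification, spec: RewardSpec) -> float:
        if notification is None:
            return 0.0
        return base * factor if notification.category == dominant else base

    return fn


@dataclass(frozen=True)
class TrainingConfig:
    folds: int = 5
    episodes_per_fold: int = 60
    search_budget: int = 10
    early_stop_patience: int = 3
    #: relative validation-reward improvement below which a fold has plateaued
    plateau_tol: float = 0.01
    eval_every: int = 10
    n_eval_users: int = 20
    weeks: int = 12
    seed: int = 0
    reward_spec: RewardSpec = RewardSpec()
    persona_config: PersonaConfig = PersonaConfig()
    search_space: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "learning_rate": LEARNING_RATE_RANGE,
            "discount": DISCOUNT_RANGE,
            "epsilon_decay": EPSILON_DECAY_RANGE,
        }
    )

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        bounds = {
            "learning_rate": LEARNING_RATE_RANGE,
            "discount": DISCOUNT_RANGE,
            "epsilon_decay": EPSILON_DECAY_RANGE,
        }
        for name, (lo, hi) in self.search_space.items():
            blo, bhi = bounds.get(name, (lo, hi))
            if lo < blo or hi > bhi:
                raise ValueError(
                    f"search range for {name} [{lo}, {hi}] outside allowed [{blo}, {bhi}]"
                )


@dataclass
class TrainingDiagnostics:
    """Per-episode reward and per-update TD-loss series plus run metadata."""

    episode_rewards: pd.DataFrame  # fold, episode, reward
    td_losses: pd.DataFrame  # fold, update, loss
    validation: pd.DataFrame  # fold, episode, mean_validation_reward
    best_fold: int = -1
    best_validation_reward: float = float("nan")
    stopped_at_episode: dict[int, int] = field(default_factory=dict)
    best_hyperparams: Optional[AgentHyperparams] = None

    def write_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.episode_rewards.to_csv(d / "episode_rewards.csv", index=False)
        self.td_losses.to_csv(d / "td_losses.csv", index=False)
        self.validation.to_csv(d / "validation_rewards.csv", index=False)

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        if not self.episode_rewards.empty:
            for fold, grp in self.episode_rewards.groupby("fold"):
                axes[0].plot(grp["episode"], grp["reward"].rolling(10, min_periods=1).mean(),
                             alpha=0.7, label=f"fold {fold}")
        axes[0].set_xlabel("episode")
        axes[0].set_ylabel("episodic reward (rolling mean)")
        axes[0].legend(fontsize=7)
        if not self.td_losses.empty:
            axes[1].semilogy(self.td_losses["update"], self.td_losses["loss"], lw=0.5)
        axes[1].set_xlabel("update")
        axes[1].set_ylabel("mean TD loss")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def fit_scaler(
    cohort: Sequence[UserSeed],
    config: TrainingConfig = TrainingConfig(),
    n_users: int = 30,
) -> "agent_mod.FeatureScaler":
    """Freeze feature-scaling bounds from an agent-free warmup simulation."""
    from .persona import FeatureScaler

    rng = np.random.default_rng(config.seed)
    vectors = []
    for seed in cohort[:n_users]:
        state = UserState(seed=seed, level=seed.baseline_weekly_units)
        history = history_from_seed(seed)
        for week in range(1, config.weeks + 1):
            if state.attrited:
                break
            result = step_week(state, [], rng)
            history.diary.extend(result.diary)
            history.events.extend(result.events)
            if result.questionnaire is not None:
                history.questionnaires.append(result.questionnaire)
            as_of = (history.signup_day + DAYS_PER_WEEK * week) * MINUTES_PER_DAY
            vectors.append(build_persona(history, as_of, config.persona_config).values)
    return FeatureScaler().fit(vectors)


def _sent_record(
    policy: PolicyState,
    category: NotificationCategory,
    segment_id: Optional[str],
    minute: int,
) -> Optional[NotificationRecord]:
    if category in (NotificationCategory.no_message,) or segment_id is None:
        return None
    seg = policy.action_space.segment(segment_id)
    return NotificationRecord(
        minute=minute, category=category, segment_id=segment_id, bct_tag=seg.bct_tag
    )


def run_episode(
    seed: UserSeed,
    policy: PolicyState,
    rng: np.random.Generator,
    config: TrainingConfig = TrainingConfig(),
    reward_fn: RewardFn = default_reward_fn,
    greedy: bool = False,
    learn: bool = False,
    replay: Optional[list[Transition]] = None,
) -> tuple[PolicyState, float, list[float]]:
    """Simulate one user-trajectory under the policy.

    One decision per user-day; weekly behavior is resolved by the
    simulator, after which each day's decision receives its reward and a
    transition into the next day's state. With ``learn=True`` a TD update
    runs per decision once the replay buffer covers a batch. Returns the
    (possibly updated) policy, total episodic reward, and TD losses.
    """
    eff_policy = replace(policy, epsilon=0.0) if greedy else policy
    state = UserState(seed=seed, level=seed.baseline_weekly_units)
    history = history_from_seed(seed)
    spec = config.reward_spec
    hp = policy.hyperparams
    total = 0.0
    losses: list[float] = []
    cats = list(policy.action_space.categories)

    for week in range(1, config.weeks + 1):
        if state.attrited:
            break
        week_start_day = seed.signup_minute // MINUTES_PER_DAY + DAYS_PER_WEEK * (week - 1)
        notifications: list[NotificationRecord] = []
        decisions: list[tuple[np.ndarray, int, Optional[NotificationRecord]]] = []
        for d in range(DAYS_PER_WEEK):
            minute = (week_start_day + d) * MINUTES_PER_DAY + DECISION_HOUR * MINUTES_PER_HOUR
            if minute < seed.signup_minute:
                continue
            persona = build_persona(history, minute, config.persona_config)
            recent = history.notifications + notifications
            category, segment_id = agent_mod.select_action(
                eff_policy, persona, recent=recent, rng=rng, now_minute=minute
            )
            record = _sent_record(policy, category, segment_id, minute)
            if record is not None:
                notifications.append(record)
            action_idx = cats.index(category) if category in cats else 1
            decisions.append((persona.values.copy(), action_idx, record))

        result = step_week(state, notifications, rng)
        history.diary.extend(result.diary)
        history.events.extend(result.events)
        history.notifications.extend(result.notifications)
        if result.questionnaire is not None:
            history.questionnaires.append(result.questionnaire)

        resolved = {nr.minute: nr for nr in result.notifications}
        for i, (vec, action_idx, record) in enumerate(decisions):
            sent = resolved.get(record.minute) if record is not None else None
            r = reward_fn(history, sent, spec)
            total += r
            if sent is not None and sent.segment_id is not None:
                policy = agent_mod.update_posterior(
                    policy, sent.segment_id, sent.engaged_within_1h
                )
                eff_policy = replace(policy, epsilon=eff_policy.epsilon)
            terminal = state.attrited and i == len(decisions) - 1 and week == config.weeks
            nxt = decisions[i + 1][0] if i + 1 < len(decisions) else None
            if learn and replay is not None:
                replay.append(
                    Transition(
                        state=vec,
                        action=action_idx,
                        reward=r,
                        next_state=nxt if nxt is not None else vec,
                        terminal=terminal or nxt is None and week == config.weeks,
                    )
                )
                if len(replay) > hp.replay_capacity:
                    del replay[0]
                if len(replay) >= hp.batch_size:
                    idx = rng.integers(0, len(replay), size=hp.batch_size)
                    batch = [replay[j] for j in idx]
                    policy, loss = agent_mod.td_update(policy, batch)
                    eff_policy = replace(policy, epsilon=eff_policy.epsilon)
                    losses.append(loss)

    if learn:
        policy = agent_mod.decay_epsilon(policy)
    return policy, total, losses


def _evaluate(
    policy: PolicyState,
    users: Sequence[UserSeed],
    config: TrainingConfig,
    reward_fn: RewardFn,
    seed: int,
) -> float:
    """Mean greedy episodic reward over held-out users (fixed eval seed)."""
    rewards = []
    for i, user in enumerate(users[: config.n_eval_users]):
        rng = np.random.default_rng([seed, i])
        _, total, _ = run_episode(
            user, policy, rng, config, reward_fn=reward_fn, greedy=True, learn=False
        )
        rewards.append(total)
    return float(np.mean(rewards)) if rewards else 0.0


def train(
    policy_init: PolicyState,
    cohort: Sequence[UserSeed],
    config: TrainingConfig = TrainingConfig(),
    reward_fn: RewardFn = default_reward_fn,
) -> tuple[PolicyState, TrainingDiagnostics]:
    """K-fold training with early stopping; returns the policy with the
    best validation reward and the full diagnostic series."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    users = list(cohort)
    n = len(users)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)

    ep_rows, loss_rows, val_rows = [], [], []
    best_policy = policy_init
    best_val = -np.inf
    diagnostics = TrainingDiagnostics(
        episode_rewards=pd.DataFrame(),
        td_losses=pd.DataFrame(),
        validation=pd.DataFrame(),
    )

    fold_sizes = np.full(config.folds, n // config.folds)
    fold_sizes[: n % config.folds] += 1
    starts = np.concatenate([[0], np.cumsum(fold_sizes)])

    update_counter = 0
    for fold in range(config.folds):
        val_idx = perm[starts[fold] : starts[fold + 1]]
        train_idx = np.setdiff1d(perm, val_idx)
        train_users = [users[i] for i in train_idx]
        val_users = [users[i] for i in val_idx]
        if not train_users or not val_users:
            continue

        policy = replace(
            policy_init,
            q_network=policy_init.q_network.copy(),
            target_network=policy_init.target_network.copy(),
            epsilon=policy_init.hyperparams.epsilon_init,
            posteriors=dict(policy_init.posteriors),
        )
        replay: list[Transition] = []
        best_fold_val = _evaluate(policy, val_users, config, reward_fn, config.seed + 1000 + fold)
        evals_since_improve = 0
        n_evals = 0
        stopped_at = config.episodes_per_fold

        for ep in range(config.episodes_per_fold):
            user = train_users[int(rng.integers(len(train_users)))]
            policy, total, losses = run_episode(
                user, policy, rng, config, reward_fn=reward_fn, learn=True, replay=replay
            )
            ep_rows.append({"fold": fold, "episode": ep, "reward": total})
            for loss in losses:
                loss_rows.append({"fold": fold, "update": update_counter, "loss": loss})
                update_counter += 1

            if (ep + 1) % config.eval_every == 0 or ep == config.episodes_per_fold - 1:
                val = _evaluate(policy, val_users, config, reward_fn, config.seed + 1000 + fold)
                val_rows.append({"fold": fold, "episode": ep, "mean_validation_reward": val})
                n_evals += 1
                improved = val > best_fold_val * (1 + config.plateau_tol) if best_fold_val > 0 \
                    else val > best_fold_val + abs(best_fold_val) * config.plateau_tol + 1e-12
                if improved:
                    best_fold_val = val
                    evals_since_improve = 0
                else:
                    evals_since_improve += 1
                if val > best_val:
                    best_val = val
                    best_policy = policy
                    diagnostics.best_fold = fold
                if (
                    n_evals > config.early_stop_patience
                    and evals_since_improve >= config.early_stop_patience
                ):
                    stopped_at = ep + 1
                    break
        diagnostics.stopped_at_episode[fold] = stopped_at

    diagnostics.episode_rewards = pd.DataFrame(ep_rows)
    diagnostics.td_losses = pd.DataFrame(loss_rows)
    diagnostics.validation = pd.DataFrame(val_rows)
    diagnostics.best_validation_reward = best_val
    return best_policy, diagnostics


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


def _assert_in_space(sample: dict[str, float], space: dict[str, tuple[float, float]]) -> None:
    for name, value in sample.items():
        lo, hi = space[name]
        if not (lo <= value <= hi):
            raise AssertionError(f"proposed {name}={value} outside [{lo}, {hi}]")


def tune(
    objective: Callable[[AgentHyperparams], float],
    search_space: Optional[dict[str, tuple[float, float]]] = None,
    budget: int = 10,
    seed: int = 0,
    base: AgentHyperparams = AgentHyperparams(),
) -> tuple[AgentHyperparams, pd.DataFrame]:
    """Sequential model-based maximization of ``objective`` over the space.

    Learning rate is searched on a log scale. With budget < 5 the search
    is pure random; beyond that a GP surrogate proposes by expected
    improvement over random candidate pools. Returns the argmax candidate
    and the full evaluation trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = search_space or {
        "learning_rate": LEARNING_RATE_RANGE,
        "discount": DISCOUNT_RANGE,
        "epsilon_decay": EPSILON_DECAY_RANGE,
    }
    if not space:
        raise ValueError("search space must be non-empty")
    names = sorted(space)
    rng = np.random.default_rng(seed)

    def to_unit(sample: dict[str, float]) -> np.ndarray:
        out = []
        for nm in names:
            lo, hi = space[nm]
            if nm == "learning_rate":
                out.append((np.log(sample[nm]) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                out.append((sample[nm] - lo) / (hi - lo) if hi > lo else 0.5)
        return np.array(out)

    def from_unit(u: np.ndarray) -> dict[str, float]:
        sample = {}
        for i, nm in enumerate(names):
            lo, hi = space[nm]
            if nm == "learning_rate":
                sample[nm] = float(np.exp(np.log(lo) + u[i] * (np.log(hi) - np.log(lo))))
            else:
                sample[nm] = float(lo + u[i] * (hi - lo))
            sample[nm] = float(np.clip(sample[nm], lo, hi))
        return sample

    X: list[np.ndarray] = []
    y: list[float] = []
    trace = []
    for it in range(budget):
        if it < 5 or len(X) < 5:
            u = rng.random(len(names))
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6, random_state=0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.array(X), np.array(y))
            pool = rng.random((256, len(names)))
            mu, sd = gp.predict(pool, return_std=True)
            best = max(y)
            imp = mu - best
            zscore = np.divide(imp, sd, out=np.zeros_like(imp), where=sd > 0)
            ei = imp * stats.norm.cdf(zscore) + sd * stats.norm.pdf(zscore)
            u = pool[int(np.argmax(ei))]
        sample = from_unit(u)
        _assert_in_space(sample, space)
        hp = replace(base, **sample)
        score = objective(hp)
        X.append(to_unit(sample))
        y.append(score)
        trace.append({**sample, "objective": score, "iteration": it})

    best_i = int(np.argmax(y))
    best_hp = replace(base, **{nm: trace[best_i][nm] for nm in names})
    return best_hp, pd.DataFrame(trace)
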