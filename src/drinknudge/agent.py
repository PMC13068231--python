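"""The decision core: a deep Q-network over persona states.

The agent maps the scaled persona vector to one value per message
*category* (no message, generic, personalized, personalized event). An
epsilon-greedy policy with multiplicative decay handles the
exploration/exploitation trade-off at the category level; within the
chosen category, a Beta-Bernoulli Thompson draw per message *segment*
selects which placeholder message to send, so segment effectiveness keeps
adapting after the network is frozen. Declarative co-occurrence rules
remove (category, segment) candidates whose BCT tag must not appear close
to a recently sent tag.

The Q-network is a compact fully-connected ReLU network held as plain
numpy arrays, trained by stochastic gradient descent on the squared
temporal-difference error against a lagged target network — the standard
DQN recipe, sized for CPU training in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .persona import FeatureScaler, PersonaFeatures
from .records import (
    ACTION_CATEGORIES,
    MINUTES_PER_HOUR,
    NotificationCategory,
    NotificationRecord,
)

__all__ = [
    "MessageSegment",
    "ActionSpace",
    "AgentHyperparams",
    "CoOccurrenceRule",
    "QNetwork",
    "PolicyState",
    "Transition",
    "q_values",
    "select_action",
    "decay_epsilon",
    "td_update",
    "update_posterior",
    "save_policy",
    "load_policy",
    "default_action_space",
]

# hyperparameter ranges the tuner must respect
LEARNING_RATE_RANGE = (0.001, 0.1)
DISCOUNT_RANGE = (0.7, 0.95)
EPSILON_DECAY_RANGE = (0.95, 0.99)


@dataclass(frozen=True)
class MessageSegment:
    """A placeholder message identifier tagged by BCT theme (no text shipped)."""

    segment_id: str
    category: NotificationCategory
    bct_tag: str


@dataclass(frozen=True)
class ActionSpace:
    categories: tuple[NotificationCategory, ...] = ACTION_CATEGORIES
    segments: tuple[MessageSegment, ...] = ()

    def segments_for(self, category: NotificationCategory) -> list[MessageSegment]:
        return [s for s in self.segments if s.category == category]

    def segment(self, segment_id: str) -> MessageSegment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(f"unknown segment: {segment_id}")


def default_action_space() -> ActionSpace:
    """Placeholder message bank: identifiers keyed by BCT category."""
    segs = []
    bank = {
        NotificationCategory.generic: [
            ("gen_selfmon", "self_monitoring"),
            ("gen_info", "credible_source"),
            ("gen_goal", "goal_setting"),
        ],
        NotificationCategory.personalized: [
            ("per_goal", "goal_setting"),
            ("per_feedback", "feedback_on_behavior"),
            ("per_substitute", "behavior_substitution"),
            ("per_social", "social_support"),
        ],
        NotificationCategory.personalized_event: [
            ("evt_streak", "self_reward"),
            ("evt_risk", "problem_solving"),
        ],
    }
    for cat, pairs in bank.items():
        for sid, tag in pairs:
            segs.append(MessageSegment(sid, cat, tag))
    return ActionSpace(segments=tuple(segs))


@dataclass(frozen=True)
class AgentHyperparams:
    learning_rate: float = 0.01
    discount: float = 0.9
    epsilon_decay: float = 0.97
    epsilon_init: float = 1.0
    epsilon_min: float = 0.05
    hidden_layers: tuple[int, ...] = (64, 64)
    replay_capacity: int = 10_000
    batch_size: int = 32
    target_sync_every: int = 100
    grad_clip_norm: float = 10.0

    def __post_init__(self) -> None:
        checks = (
            ("learning_rate", self.learning_rate, LEARNING_RATE_RANGE),
            ("discount", self.discount, DISCOUNT_RANGE),
            ("epsilon_decay", self.epsilon_decay, EPSILON_DECAY_RANGE),
        )
        for name, val, (lo, hi) in checks:
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside allowed range [{lo}, {hi}]")
        if self.epsilon_min > self.epsilon_init:
            raise ValueError("epsilon_min must not exceed epsilon_init")


@dataclass(frozen=True)
class CoOccurrenceRule:
    """Two BCT tags that must not appear within ``window_h`` of each other."""

    tag_a: str
    tag_b: str
    window_h: float = 24.0


class QNetwork:
    """Fully-connected ReLU network: state vector -> one value per category."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.weights = weights
        self.biases = biases

    @classmethod
    def init(
        cls,
        n_in: int,
        hidden: Sequence[int],
        n_out: int,
        rng: np.random.Generator,
        scale: Optional[float] = None,
    ) -> "QNetwork":
        sizes = [n_in, *hidden, n_out]
        weights, biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            s = scale if scale is not None else np.sqrt(2.0 / a)
            weights.append(rng.normal(0.0, s, size=(a, b)))
            biases.append(np.zeros(b))
        return cls(weights, biases)

    @classmethod
    def zeros(cls, n_in: int, hidden: Sequence[int], n_out: int) -> "QNetwork":
        sizes = [n_in, *hidden, n_out]
        return cls(
            [np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])],
            [np.zeros(b) for b in sizes[1:]],
        )

    @property
    def n_in(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(x, dtype=float))
        if h.shape[1] != self.n_in:
            raise ValueError(f"state length {h.shape[1]} != network input {self.n_in}")
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[0] if np.ndim(x) == 1 else out

    def copy(self) -> "QNetwork":
        return QNetwork([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def sgd_step(
        self,
        x: np.ndarray,
        actions: np.ndarray,
        targets: np.ndarray,
        lr: float,
        clip_norm: float = 10.0,
    ) -> float:
        """One SGD step on mean squared TD error over a batch; returns the loss.

        Only the Q-value of the taken action receives gradient, as in DQN.
        Gradients are rescaled to a global norm of at most ``clip_norm``,
        which keeps updates stable when rewards or states are large.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        acts = [x]
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        q = h @ self.weights[-1] + self.biases[-1]

        picked = q[np.arange(n), actions]
        err = picked - targets
        loss = float(np.mean(err**2))

        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = 2.0 * err / n

        grad = dq
        gWs: list[np.ndarray] = []
        gbs: list[np.ndarray] = []
        for i in range(len(self.weights) - 1, -1, -1):
            gWs.append(acts[i].T @ grad)
            gbs.append(grad.sum(axis=0))
            if i > 0:
                grad = (grad @ self.weights[i].T) * (acts[i] > 0)
        gWs.reverse()
        gbs.reverse()
        if clip_norm is not None and clip_norm > 0:
            total = np.sqrt(
                sum(float((g**2).sum()) for g in gWs) + sum(float((g**2).sum()) for g in gbs)
            )
            if total > clip_norm:
                scale = clip_norm / total
                gWs = [g * scale for g in gWs]
                gbs = [g * scale for g in gbs]
        for i in range(len(self.weights)):
            self.weights[i] -= lr * gWs[i]
            self.biases[i] -= lr * gbs[i]
        return loss


@dataclass
class PolicyState:
    """Everything the deployed agent carries: network, exploration, posteriors, rules."""

    q_network: QNetwork
    target_network: QNetwork
    action_space: ActionSpace
    hyperparams: AgentHyperparams
    epsilon: float
    posteriors: dict[str, tuple[float, float]]  # segment_id -> Beta(alpha, beta)
    rules: tuple[CoOccurrenceRule, ...] = ()
    scaler: FeatureScaler = field(default_factory=FeatureScaler)
    rng_seed: int = 0
    updates_done: int = 0

    @classmethod
    def fresh(
        cls,
        n_features: int,
        hyperparams: AgentHyperparams = AgentHyperparams(),
        action_space: Optional[ActionSpace] = None,
        rules: tuple[CoOccurrenceRule, ...] = (),
        seed: int = 0,
        zero_init: bool = False,
    ) -> "PolicyState":
        space = action_space or default_action_space()
        rng = np.random.default_rng(seed)
        n_out = len(space.categories)
        if zero_init:
            net = QNetwork.zeros(n_features, hyperparams.hidden_layers, n_out)
        else:
            net = QNetwork.init(n_features, hyperparams.hidden_layers, n_out, rng)
        return cls(
            q_network=net,
            target_network=net.copy(),
            action_space=space,
            hyperparams=hyperparams,
            epsilon=hyperparams.epsilon_init,
            posteriors={s.segment_id: (1.0, 1.0) for s in space.segments},
            rules=rules,
            rng_seed=seed,
        )


@dataclass(frozen=True)
class Transition:
    state: np.ndarray
    action: int  # index into action_space.categories
    reward: float
    next_state: Optional[np.ndarray]
    terminal: bool


def q_values(policy: PolicyState, state: PersonaFeatures | np.ndarray) -> np.ndarray:
    """Deterministic per-category action values for one state."""
    if isinstance(state, PersonaFeatures):
        if not state.available:
            raise ValueError("persona unavailable: the agent must not be consulted")
        vec = state.values
    else:
        vec = state
    return np.asarray(policy.q_network.forward(policy.scaler.transform(vec)), dtype=float)


def _recent_tags(
    recent: Sequence[NotificationRecord], now_minute: int, rule: CoOccurrenceRule
) -> set[str]:
    horizon = now_minute - rule.window_h * MINUTES_PER_HOUR
    return {
        nr.bct_tag
        for nr in recent
        if nr.bct_tag is not None and horizon <= nr.minute <= now_minute
    }


def _permitted_segments(
    policy: PolicyState,
    category: NotificationCategory,
    recent: Sequence[NotificationRecord],
    now_minute: int,
) -> list[MessageSegment]:
    segs = policy.action_space.segments_for(category)
    for rule in policy.rules:
        tags = _recent_tags(recent, now_minute, rule)
        banned = set()
        if rule.tag_a in tags:
            banned.add(rule.tag_b)
        if rule.tag_b in tags:
            banned.add(rule.tag_a)
        segs = [s for s in segs if s.bct_tag not in banned]
    return segs


def select_action(
    policy: PolicyState,
    state: PersonaFeatures,
    recent: Sequence[NotificationRecord] = (),
    rng: Optional[np.random.Generator] = None,
    now_minute: Optional[int] = None,
) -> tuple[NotificationCategory, Optional[str]]:
    """Choose a (category, segment) for one decision point.

    Unavailable personas short-circuit to scheduled generic messaging.
    Otherwise: epsilon-greedy over the permitted categories on the
    Q-values, then a Thompson draw from each candidate segment's Beta
    posterior picks the segment within the chosen category. Candidates
    violating a co-occurrence rule against ``recent`` are removed before
    selection; if nothing survives, no message is sent.
    """
    rng = rng if rng is not None else np.random.default_rng(policy.rng_seed)
    now = now_minute if now_minute is not None else state.as_of

    def pick_segment(category: NotificationCategory) -> Optional[str]:
        segs = _permitted_segments(policy, category, recent, now)
        if not segs:
            return None
        draws = [rng.beta(*policy.posteriors[s.segment_id]) for s in segs]
        return segs[int(np.argmax(draws))].segment_id

    if not state.available:
        seg = pick_segment(NotificationCategory.generic)
        return NotificationCategory.generic, seg

    cats = list(policy.action_space.categories)
    permitted = [
        c
        for c in cats
        if c == NotificationCategory.no_message
        or _permitted_segments(policy, c, recent, now)
    ]
    if permitted == [NotificationCategory.no_message] or not permitted:
        return NotificationCategory.no_message, None

    if rng.random() < policy.epsilon:
        category = permitted[int(rng.integers(len(permitted)))]
    else:
        q = q_values(policy, state)
        idx = max(
            (i for i, c in enumerate(cats) if c in permitted),
            key=lambda i: q[i],
        )
        category = cats[idx]

    if category == NotificationCategory.no_message:
        return category, None
    return category, pick_segment(category)


def decay_epsilon(policy: PolicyState) -> PolicyState:
    """Multiplicative decay with a floor: eps <- max(eps_min, eps * decay)."""
    hp = policy.hyperparams
    new_eps = max(hp.epsilon_min, policy.epsilon * hp.epsilon_decay)
    return replace(policy, epsilon=new_eps)


def td_update(
    policy: PolicyState, batch: Sequence[Transition], hp: Optional[AgentHyperparams] = None
) -> tuple[PolicyState, float]:
    """One gradient step on a batch of transitions; returns mean TD loss.

    Targets: ``y = r`` for terminal transitions, else
    ``y = r + gamma * max_a target_network(s')``. The target network is
    synced to the online network every ``target_sync_every`` updates.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    hp = hp or policy.hyperparams
    states = np.stack([policy.scaler.transform(t.state) for t in batch])
    actions = np.array([t.action for t in batch])
    rewards = np.array([t.reward for t in batch], dtype=float)

    targets = rewards.copy()
    non_terminal = [i for i, t in enumerate(batch) if not t.terminal]
    if non_terminal:
        nxt = np.stack([policy.scaler.transform(batch[i].next_state) for i in non_terminal])
        future = policy.target_network.forward(nxt).max(axis=1)
        for j, i in enumerate(non_terminal):
            targets[i] += hp.discount * future[j]

    net = policy.q_network.copy()
    loss = net.sgd_step(states, actions, targets, hp.learning_rate, clip_norm=hp.grad_clip_norm)
    updates = policy.updates_done + 1
    target = policy.target_network
    if updates % hp.target_sync_every == 0:
        target = net.copy()
    return replace(policy, q_network=net, target_network=target, updates_done=updates), loss


def update_posterior(policy: PolicyState, segment_id: str, engaged: bool) -> PolicyState:
    """Conjugate Beta update of one segment's engagement posterior."""
    if segment_id not in policy.posteriors:
        raise KeyError(f"unknown segment: {segment_id}")
    a, b = policy.posteriors[segment_id]
    posteriors = dict(policy.posteriors)
    posteriors[segment_id] = (a + 1.0, b) if engaged else (a, b + 1.0)
    return replace(policy, posteriors=posteriors)


# ---------------------------------------------------------------------------
# Checkpointing — a single JSON archive with network parameters, scaler
# bounds, posteriors, epsilon and rules; plain text so checkpoints diff.
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_policy(policy: PolicyState, path: str | Path) -> None:
    hp = policy.hyperparams
    doc = {
        "version": CHECKPOINT_VERSION,
        "hyperparams": {
            "learning_rate": hp.learning_rate,
            "discount": hp.discount,
            "epsilon_decay": hp.epsilon_decay,
            "epsilon_init": hp.epsilon_init,
            "epsilon_min": hp.epsilon_min,
            "hidden_layers": list(hp.hidden_layers),
            "replay_capacity": hp.replay_capacity,
            "batch_size": hp.batch_size,
            "target_sync_every": hp.target_sync_every,
            "grad_clip_norm": hp.grad_clip_norm,
        },
        "epsilon": policy.epsilon,
        "rng_seed": policy.rng_seed,
        "updates_done": policy.updates_done,
        "weights": [w.tolist() for w in policy.q_network.weights],
        "biases": [b.tolist() for b in policy.q_network.biases],
        "target_weights": [w.tolist() for w in policy.target_network.weights],
        "target_biases": [b.tolist() for b in policy.target_network.biases],
        "posteriors": {k: list(v) for k, v in policy.posteriors.items()},
        "rules": [[r.tag_a, r.tag_b, r.window_h] for r in policy.rules],
        "scaler": {"lo": policy.scaler.lo.tolist(), "hi": policy.scaler.hi.tolist()},
        "segments": [
            [s.segment_id, s.category.value, s.bct_tag] for s in policy.action_space.segments
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_policy(path: str | Path) -> PolicyState:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {doc.get('version')}")
    hp = AgentHyperparams(
        learning_rate=doc["hyperparams"]["learning_rate"],
        discount=doc["hyperparams"]["discount"],
        epsilon_decay=doc["hyperparams"]["epsilon_decay"],
        epsilon_init=doc["hyperparams"]["epsilon_init"],
        epsilon_min=doc["hyperparams"]["epsilon_min"],
        hidden_layers=tuple(doc["hyperparams"]["hidden_layers"]),
        replay_capacity=doc["hyperparams"]["replay_capacity"],
        batch_size=doc["hyperparams"]["batch_size"],
        target_sync_every=doc["hyperparams"]["target_sync_every"],
        grad_clip_norm=doc["hyperparams"].get("grad_clip_norm", 10.0),
    )
    space = ActionSpace(
        segments=tuple(
            MessageSegment(sid, NotificationCategory(cat), tag)
            for sid, cat, tag in doc["segments"]
        )
    )
    scaler = FeatureScaler(lo=np.asarray(doc["scaler"]["lo"]), hi=np.asarray(doc["scaler"]["hi"]))
    return PolicyState(
        q_network=QNetwork(
            [np.asarray(w) for w in doc["weights"]], [np.asarray(b) for b in doc["biases"]]
        ),
        target_network=QNetwork(
            [np.asarray(w) for w in doc["target_weights"]],
            [np.asarray(b) for b in doc["target_biases"]],
        ),
        action_space=space,
        hyperparams=hp,
        epsilon=doc["epsilon"],
        posteriors={k: (v[0], v[1]) for k, v in doc["posteriors"].items()},
        rules=tuple(CoOccurrenceRule(a, b, w) for a, b, w in doc["rules"]),
        scaler=scaler,
        rng_seed=doc["rng_seed"],
        updates_done=doc["updates_done"],
    )
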