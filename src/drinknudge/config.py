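"""Run configuration: schema-validated YAML with every default made explicit.

A run config has nested sections for the cohort generator, reward bands,
agent hyperparameters, training, the trial, and analysis, plus a global
seed and output directory. Loading resolves all defaults and can persist
the resolved copy next to the outputs, so a run is reproducible from its
own artifacts. Validation errors name the offending field and constraint
(e.g. a discount factor outside [0.7, 0.95]).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .agent import DISCOUNT_RANGE, EPSILON_DECAY_RANGE, LEARNING_RATE_RANGE, AgentHyperparams
from .persona import PersonaConfig
from .reward import RewardSpec
from .simulator import ARCHETYPES, DEFAULT_MIXTURE, CohortConfig, DemographicTargets
from .trainer import TrainingConfig
from .trial import TrialConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class CohortSection(BaseModel):
    n_users: int = 200
    archetype_mixture: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    weeks: int = 12
    signup_span_days: int = 30
    frac_missing_demographics: float = 0.037
    frac_non_veteran: float = 0.082
    baseline_below_threshold_mass: float = 0.16
    noise_sigma: float = 0.15

    @field_validator("archetype_mixture")
    @classmethod
    def _known_archetypes(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mixture weights must sum to 1, got {total}")
        return v

    def to_dataclass(self, seed: int) -> CohortConfig:
        return CohortConfig(
            n_users=self.n_users,
            archetype_mixture=self.archetype_mixture,
            seed=seed,
            weeks=self.weeks,
            signup_span_days=self.signup_span_days,
            demographics=DemographicTargets(),
            frac_missing_demographics=self.frac_missing_demographics,
            frac_non_veteran=self.frac_non_veteran,
            baseline_below_threshold_mass=self.baseline_below_threshold_mass,
            noise_sigma=self.noise_sigma,
        )


class RewardSection(BaseModel):
    engagement_band: tuple[float, float] = (1.0, 10.0)
    reduction_band: tuple[float, float] = (10.0, 20.0)
    penalty_band: tuple[float, float] = (-10.0, -5.0)
    engagement_window_h: float = 1.0
    disengagement_min_notifications: int = 3
    ramp_scale: float = 5.0
    pattern_shift_fraction: float = 0.25

    def to_dataclass(self) -> RewardSpec:
        return RewardSpec(**self.model_dump())


class AgentSection(BaseModel):
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

    @model_validator(mode="after")
    def _ranges(self) -> "AgentSection":
        for name, value, (lo, hi) in (
            ("learning_rate", self.learning_rate, LEARNING_RATE_RANGE),
            ("discount", self.discount, DISCOUNT_RANGE),
            ("epsilon_decay", self.epsilon_decay, EPSILON_DECAY_RANGE),
        ):
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside allowed range [{lo}, {hi}]")
        return self

    def to_dataclass(self) -> AgentHyperparams:
        return AgentHyperparams(**self.model_dump())


class TrainingSection(BaseModel):
    folds: int = Field(5, ge=2)
    episodes_per_fold: int = 60
    search_budget: int = 10
    early_stop_patience: int = 3
    plateau_tol: float = 0.01
    eval_every: int = 10
    n_eval_users: int = 20
    weeks: int = 12

    def to_dataclass(self, seed: int, reward: RewardSpec, persona: PersonaConfig) -> TrainingConfig:
        return TrainingConfig(
            folds=self.folds,
            episodes_per_fold=self.episodes_per_fold,
            search_budget=self.search_budget,
            early_stop_patience=self.early_stop_patience,
            plateau_tol=self.plateau_tol,
            eval_every=self.eval_every,
            n_eval_users=self.n_eval_users,
            weeks=self.weeks,
            seed=seed,
            reward_spec=reward,
            persona_config=persona,
        )


class TrialSection(BaseModel):
    weeks: int = 12
    inclusion_threshold_units: float = 14.0
    retention_min_weeks: int = 6
    retention_min_interactions_per_week: int = 3
    allocation_sequence: str = "CP"
    generic_per_week: int = 1
    daily_personalized_cap: int = 2
    max_reminders: int = 3

    def to_dataclass(self, seed: int, persona: PersonaConfig) -> TrialConfig:
        return TrialConfig(
            weeks=self.weeks,
            inclusion_threshold_units=self.inclusion_threshold_units,
            retention_min_weeks=self.retention_min_weeks,
            retention_min_interactions_per_week=self.retention_min_interactions_per_week,
            allocation_sequence=self.allocation_sequence,
            generic_per_week=self.generic_per_week,
            daily_personalized_cap=self.daily_personalized_cap,
            max_reminders=self.max_reminders,
            seed=seed,
            persona_config=persona,
        )


class PersonaSection(BaseModel):
    window_days: int = 28
    min_events_for_availability: int = 3
    binge_units: float = 6.0
    binge_min_days: int = 3
    depression_cutoff: float = 10.0
    anxiety_cutoff: float = 8.0
    loneliness_cutoff: float = 6.0
    latency_cap_h: float = 168.0

    def to_dataclass(self) -> PersonaConfig:
        return PersonaConfig(**self.model_dump())


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "runs/latest"
    cohort: CohortSection = CohortSection()
    persona: PersonaSection = PersonaSection()
    reward: RewardSection = RewardSection()
    agent: AgentSection = AgentSection()
    training: TrainingSection = TrainingSection()
    trial: TrialSection = TrialSection()


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> RunConfig:
    """Load and validate a YAML run config; an empty or absent file means
    all defaults. A ``seed`` argument overrides the file's seed."""
    doc = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
    try:
        cfg = RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ValueError(f"invalid run config: {exc}") from exc
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist the fully resolved config (every default made explicit)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
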