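"""Hierarchical simulation of optimism loss and maintenance in childhood.

A two-level model is exposed to an in-silico childhood of valence/arousal
events.  Level 1 (observation level) maps events to valence and arousal
state posteriors through identity likelihood and transition matrices; those
posteriors become the soft observations of level 2 (state level), whose
single hidden factor is the optimism state.  The valence likelihood at
level 2 is precise (optimistic state -> positive valence) and locked by
scaling its counts by 1000, so only two things are learned: the optimism
prior counts d (once per state-level trial, a "year" of 52 weekly events)
and the arousal likelihood counts a2, which start flat.

Agents that mostly see negative valence accumulate d mass on the
pessimistic state and, when high arousal co-occurs with negative valence,
learn an arousal mapping that makes high arousal evidence for pessimism —
the anxious phenotype.  Balanced exposure preserves the initial optimism
prior of [0.8, 0.2] and keeps the arousal mapping near flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import infer_states
from .learning import optimism_level, update_a, update_d
from .model import (
    DirichletCounts,
    GenerativeModel,
    Modality,
    StateFactor,
    lock_precision,
    one_hot,
)

__all__ = [
    "DevelopmentConfig",
    "DevelopmentResult",
    "generate_environment",
    "run_level1",
    "build_state_level_model",
    "run_development",
    "run_cohort",
]

# category order: positive before negative, high arousal before low,
# optimistic before pessimistic
VALENCE_STATES = ("positive", "negative")
AROUSAL_STATES = ("high", "low")
OPTIMISM_STATES = ("optimistic", "pessimistic")


@dataclass(frozen=True)
class DevelopmentConfig:
    """Study conditions for the developmental cohort.

    Five state-level trials ("years") of 52 observation-level trials
    ("weeks") each; 200 agents with per-agent probabilities of negative
    valence.  ``p_negative=None`` draws each agent's value uniformly on
    [0, 1].  ``p_couple`` is the probability of high arousal given a
    negative-valence event; ``p_high_arousal`` is the probability of high
    arousal given a positive-valence event (0.5/0.5 makes arousal
    independent of valence).
    """

    n_agents: int = 200
    obs_level_trials: int = 52
    state_level_trials: int = 5
    p_negative: float | None = None
    p_high_arousal: float = 0.5
    p_couple: float = 0.7
    valence_precision: float = 0.8
    lock_factor: float = 1000.0
    arousal_count: float = 0.25
    optimism_prior: float = 0.8
    d_mass: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_high_arousal", "p_couple", "optimism_prior"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_negative is not None and not (0.0 <= self.p_negative <= 1.0):
            raise ValueError("p_negative must lie in [0, 1]")
        if self.obs_level_trials < 1 or self.state_level_trials < 1 or self.n_agents < 1:
            raise ValueError("trial and agent counts must be >= 1")


@dataclass
class DevelopmentResult:
    """Per-agent outcome of one in-silico childhood."""

    final_optimism: float
    p_negative: float
    prop_negative: float
    prop_high_arousal: float
    arousal_likelihood: np.ndarray  # normalised a2, (arousal outcome, optimism state)
    d_trajectory: np.ndarray  # (years + 1, 2) optimism counts after each year
    posterior_trajectory: np.ndarray  # (years, weeks, 2) level-2 posteriors


def generate_environment(config: DevelopmentConfig, rng=None, p_negative: float | None = None):
    """Sample the childhood event stream: (valence, arousal) index pairs.

    Valence is Bernoulli(p_negative) (index 1 = negative); arousal is high
    (index 0) with probability ``p_couple`` after a negative event and
    ``p_high_arousal`` after a positive one.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) if not isinstance(rng, np.random.Generator) else rng
    if p_negative is None:
        p_negative = config.p_negative
    if p_negative is None:
        raise ValueError("p_negative must be given in the config or as an argument")
    n = config.obs_level_trials * config.state_level_trials
    valence = (rng.random(n) < p_negative).astype(int)  # 1 = negative
    p_high = np.where(valence == 1, config.p_couple, config.p_high_arousal)
    arousal = (rng.random(n) >= p_high).astype(int)  # 0 = high, 1 = low
    return valence, arousal


def _level1_model(A1: np.ndarray) -> GenerativeModel:
    identity_B = np.eye(2)[:, :, None]
    factor = StateFactor("state", DirichletCounts(np.array([0.5, 0.5]), learnable=False), identity_B)
    mod = Modality("outcome", DirichletCounts(np.asarray(A1, dtype=float), learnable=False))
    return GenerativeModel(factors=[factor], modalities=[mod], policies=np.zeros((1, 0, 1), int), horizon=1)


def run_level1(events, A1: np.ndarray | None = None) -> np.ndarray:
    """Observation-level inference: one 2-state posterior per event.

    With the identity likelihood and transition matrices the posteriors are
    the event one-hots (to tolerance); a perturbed ``A1`` gives the exact
    Bayes posterior under a uniform prior.  These posteriors are the soft
    observations consumed by the state level.
    """
    events = np.asarray(events, dtype=int)
    if events.size == 0:
        raise ValueError("empty event list")
    model = _level1_model(np.eye(2) if A1 is None else A1)
    posteriors = np.empty((events.shape[0], 2))
    for i, e in enumerate(events):
        belief = infer_states(model, [[one_hot(int(e), 2)]])
        posteriors[i] = belief.s[0]
    return posteriors


def build_state_level_model(config: DevelopmentConfig, horizon: int | None = None) -> GenerativeModel:
    """Level-2 model: optimism factor, locked valence and flat arousal maps."""
    horizon = config.obs_level_trials if horizon is None else horizon
    d = DirichletCounts(
        np.array([config.optimism_prior, 1.0 - config.optimism_prior]) * config.d_mass,
        learnable=True,
    )
    factor = StateFactor("optimism", d, np.eye(2)[:, :, None])
    q = config.valence_precision
    valence_a = lock_precision(
        DirichletCounts(np.array([[q, 1.0 - q], [1.0 - q, q]])), config.lock_factor
    )
    arousal_a = DirichletCounts(np.full((2, 2), config.arousal_count), learnable=True)
    return GenerativeModel(
        factors=[factor],
        modalities=[Modality("valence", valence_a), Modality("arousal", arousal_a)],
        policies=np.zeros((1, max(horizon - 1, 0), 1), int),
        horizon=horizon,
    )


def run_development(
    config: DevelopmentConfig, rng=None, p_negative: float | None = None
) -> DevelopmentResult:
    """Run one agent's childhood and return its final optimism and a2.

    Each year presents 52 level-1 posteriors as sequential level-2
    observations under an identity transition (the agent stays optimistic
    or pessimistic within the year); d is updated once per year from the
    year's first-timestep posterior, and the arousal counts accumulate the
    year's observation-posterior outer products.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) if not isinstance(rng, np.random.Generator) else rng
    valence, arousal = generate_environment(config, rng=rng, p_negative=p_negative)
    valence_post = run_level1(valence)
    arousal_post = run_level1(arousal)

    model = build_state_level_model(config)
    weeks = config.obs_level_trials
    years = config.state_level_trials
    d_traj = np.empty((years + 1, 2))
    d_traj[0] = model.factor("optimism").d.values
    post_traj = np.empty((years, weeks, 2))

    for year in range(years):
        lo, hi = year * weeks, (year + 1) * weeks
        obs = [[valence_post[t], arousal_post[t]] for t in range(lo, hi)]
        belief = infer_states(model, obs)
        post_traj[year] = belief.s
        new_d = update_d(model.factor("optimism").d, belief.s[0])
        model.replace_factor("optimism", d=new_d)
        new_a = update_a(model.modality("arousal").a, [arousal_post[t] for t in range(lo, hi)], list(belief.s))
        model.replace_modality("arousal", a=new_a)
        d_traj[year + 1] = new_d.values

    return DevelopmentResult(
        final_optimism=optimism_level(model.factor("optimism").d),
        p_negative=float(config.p_negative if p_negative is None else p_negative),
        prop_negative=float(np.mean(valence == 1)),
        prop_high_arousal=float(np.mean(arousal == 0)),
        arousal_likelihood=model.modality("arousal").a.normalized(),
        d_trajectory=d_traj,
        posterior_trajectory=post_traj,
    )


def run_cohort(config: DevelopmentConfig) -> pd.DataFrame:
    """Simulate the cohort; one row per agent.

    Each agent gets an independent random stream spawned from the master
    seed, and (unless fixed in the config) a uniformly drawn probability of
    negative events, giving broad coverage of developmental environments.
    """
    if config.n_agents < 2:
        raise ValueError("a cohort needs at least two agents")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_agents + 1)
    draw_rng = np.random.default_rng(children[-1])
    rows = []
    for i in range(config.n_agents):
        rng = np.random.default_rng(children[i])
        p_neg = config.p_negative if config.p_negative is not None else float(draw_rng.random())
        res = run_development(config, rng=rng, p_negative=p_neg)
        a2 = res.arousal_likelihood
        rows.append(
            {
                "agent": i,
                "p_negative": p_neg,
                "prop_negative": res.prop_negative,
                "prop_high_arousal": res.prop_high_arousal,
                "final_optimism": res.final_optimism,
                "a2_high_given_optimistic": a2[0, 0],
                "a2_high_given_pessimistic": a2[0, 1],
            }
        )
    return pd.DataFrame(rows)
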