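"""Categorical POMDP building blocks shared by every simulation.

The agent's beliefs are a *generative model*: per-factor state priors ``D``
(with Dirichlet counts ``d``), per-modality likelihood tables ``A`` (with
Dirichlet counts ``a``), per-factor transition tables ``B``, log-domain
outcome preferences ``C`` and a set of allowed policies.  The environment is
a *generative process*: structurally identical tables whose parameters may
differ from the agent's beliefs, plus a seeded outcome sampler.

Category-order conventions are fixed globally: good/positive outcomes come
before bad/negative ones and the optimistic state precedes the pessimistic
state.  Indices are 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EPS",
    "stable_log",
    "softmax",
    "log_softmax",
    "as_categorical",
    "DirichletCounts",
    "StateFactor",
    "Modality",
    "GenerativeModel",
    "GenerativeProcess",
    "normalize",
    "make_biased_likelihood",
    "biased_likelihood_pair",
    "lock_precision",
    "transpose_normalized",
]

#: additive log stabiliser; identity mappings contain exact zeros
EPS = 1e-16

#: locking factor at or above which a Dirichlet block is treated as frozen
LOCK_THRESHOLD = 100.0

CATEGORICAL_TOL = 1e-10


def stable_log(x: np.ndarray) -> np.ndarray:
    """Natural log with an additive floor so exact zeros stay finite."""
    return np.log(np.asarray(x, dtype=float) + EPS)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - np.max(x, axis=axis, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=axis, keepdims=True))


def as_categorical(p, name: str = "vector") -> np.ndarray:
    """Validate and return a probability vector (entries >= 0, unit sum)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {p.shape}")
    if np.any(p < -CATEGORICAL_TOL):
        raise ValueError(f"{name} has negative entries: {p}")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=CATEGORICAL_TOL, rtol=0.0):
        raise ValueError(f"{name} does not sum to 1 (sum={s!r})")
    return np.clip(p, 0.0, None)


def normalize(counts) -> np.ndarray:
    """Expectation of a Dirichlet block: divide each column by its sum.

    ``counts`` may be a :class:`DirichletCounts`, a 1-D vector, or a table
    whose leading axis indexes outcomes (columns are summed over axis 0).
    """
    values = counts.values if isinstance(counts, DirichletCounts) else np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("Dirichlet counts must be non-negative")
    sums = values.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("degenerate Dirichlet counts: a column sums to zero")
    return values / sums


@dataclass(frozen=True)
class DirichletCounts:
    """Concentration parameters of a categorical block plus a learnable flag.

    The leading axis indexes outcome/state categories; trailing axes are the
    conditioning state configuration.  Counts never decrease under learning.
    """

    values: np.ndarray
    learnable: bool = True

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("Dirichlet counts must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def normalized(self) -> np.ndarray:
        return normalize(self.values)

    def scaled(self, factor: float) -> "DirichletCounts":
        return lock_precision(self, factor)


def lock_precision(counts: DirichletCounts, factor: float) -> DirichletCounts:
    """Scale counts by ``factor`` (>= 1), freezing the block when large.

    Multiplying the counts leaves the normalised mapping unchanged while
    making unit-count updates negligible; the learnable flag is cleared once
    ``factor`` exceeds the locking threshold.
    """
    if factor < 1:
        raise ValueError("lock factor must be >= 1")
    learnable = counts.learnable and factor < LOCK_THRESHOLD
    return DirichletCounts(counts.values * float(factor), learnable=learnable)


def make_biased_likelihood(a_good: float, a_bad: float) -> np.ndarray:
    """2x2 outcome-by-belief-state likelihood for the *optimistic* state.

    Rows are (good news, bad news); columns are (good outcome, bad outcome)::

        [[a_good,     1 - a_bad],
         [1 - a_good, a_bad    ]]

    ``a_good`` is the probability of good news given the good outcome and
    ``a_bad`` the probability of bad news given the bad outcome.
    """
    for name, v in (("a_good", a_good), ("a_bad", a_bad)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {v}")
    return np.array([[a_good, 1.0 - a_bad], [1.0 - a_good, a_bad]], dtype=float)


def biased_likelihood_pair(a_good: float, a_bad: float) -> np.ndarray:
    """Stack the optimistic slice with its pessimistic mirror.

    Returns shape (outcome, belief-state, optimism-state).  The pessimistic
    slice swaps the roles of the good and bad precisions, so a pessimist is
    precise about bad news exactly as an optimist is about good news.
    """
    opt = make_biased_likelihood(a_good, a_bad)
    pess = make_biased_likelihood(a_bad, a_good)
    return np.stack([opt, pess], axis=2)


def transpose_normalized(B: np.ndarray) -> np.ndarray:
    """Companion matrix B-dagger: transpose of B with columns renormalised.

    Columns of the transpose that sum to zero (states unreachable under a
    deterministic mapping) are replaced by uniform columns, which makes the
    corresponding backward message uninformative.
    """
    Bt = np.asarray(B, dtype=float).T.copy()
    sums = Bt.sum(axis=0)
    dead = sums <= 0
    if np.any(dead):
        Bt[:, dead] = 1.0 / Bt.shape[0]
        sums = Bt.sum(axis=0)
    return Bt / sums


@dataclass(frozen=True)
class StateFactor:
    """A named hidden-state factor: Dirichlet prior d and transitions B.

    ``B`` has shape (next-state, previous-state, action); every column of
    every action slice sums to 1.
    """

    name: str
    d: DirichletCounts
    B: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        n = self.d.values.shape[0]
        if self.d.values.ndim != 1:
            raise ValueError(f"factor {self.name}: d must be a vector")
        if self.B.ndim != 3 or self.B.shape[0] != n or self.B.shape[1] != n:
            raise ValueError(f"factor {self.name}: B must have shape ({n},{n},actions)")
        if not np.allclose(self.B.sum(axis=0), 1.0, atol=CATEGORICAL_TOL):
            raise ValueError(f"factor {self.name}: B columns must sum to 1")

    @property
    def n_states(self) -> int:
        return self.d.values.shape[0]

    @property
    def n_actions(self) -> int:
        return self.B.shape[2]

    def prior(self) -> np.ndarray:
        return self.d.normalized()


@dataclass(frozen=True)
class Modality:
    """A named outcome modality: Dirichlet likelihood counts a and preferences.

    ``a.values`` has shape (outcome, *factor sizes) spanning every state
    factor of the owning model.  ``preferences`` are real-valued log-domain
    weights per outcome (softmax-normalised before any logarithm is taken);
    ``None`` means the modality carries no preferences and cannot enter the
    risk term.
    """

    name: str
    a: DirichletCounts
    preferences: np.ndarray | None = None

    def __post_init__(self):
        if self.preferences is not None:
            p = np.asarray(self.preferences, dtype=float)
            if p.ndim != 1 or p.shape[0] != self.a.values.shape[0]:
                raise ValueError(f"modality {self.name}: preferences must have one weight per outcome")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"modality {self.name}: preferences must be finite")
            object.__setattr__(self, "preferences", p)

    @property
    def n_outcomes(self) -> int:
        return self.a.values.shape[0]

    def log_preferences(self) -> np.ndarray:
        if self.preferences is None:
            raise ValueError(f"modality {self.name} has no preference vector")
        return log_softmax(self.preferences)


@dataclass
class GenerativeModel:
    """The agent's joint POMDP model over one or more hidden-state factors.

    ``policies`` is an integer array of shape (n_policies, horizon - 1,
    n_factors) giving the action applied to each factor at each transition.
    Factor state spaces are combined into a joint space in C order (the
    first factor varies slowest).
    """

    factors: list[StateFactor]
    modalities: list[Modality]
    policies: np.ndarray
    horizon: int

    def __post_init__(self):
        self.policies = np.asarray(self.policies, dtype=int)
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        expected = (self.policies.shape[0], max(self.horizon - 1, 0), len(self.factors))
        if self.policies.size == 0:
            self.policies = np.zeros(expected, dtype=int)
        if self.policies.shape != expected:
            raise ValueError(f"policies must have shape {expected}, got {self.policies.shape}")
        for f_idx, f in enumerate(self.factors):
            if np.any(self.policies[:, :, f_idx] >= f.n_actions):
                raise ValueError(f"policy indexes an invalid action for factor {f.name}")
        shape = self.factor_sizes
        for m in self.modalities:
            if m.a.values.shape[1:] != shape:
                raise ValueError(
                    f"modality {m.name}: likelihood table shape {m.a.values.shape} "
                    f"inconsistent with factor sizes {shape}"
                )

    @property
    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(f.n_states for f in self.factors)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.factor_sizes))

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    def joint_prior(self) -> np.ndarray:
        p = np.ones(1)
        for f in self.factors:
            p = np.kron(p, f.prior())
        return p

    def joint_likelihood(self, m: int | str) -> np.ndarray:
        mod = self.modality(m)
        table = mod.a.normalized()
        return table.reshape(mod.n_outcomes, -1)

    def joint_transition(self, policy: int, step: int) -> np.ndarray:
        """Joint B for the transition into timestep ``step`` (1-based steps)."""
        B = np.ones((1, 1))
        for f_idx, f in enumerate(self.factors):
            action = int(self.policies[policy, step - 1, f_idx])
            B = np.kron(B, f.B[:, :, action])
        return B

    def modality(self, m: int | str) -> Modality:
        if isinstance(m, str):
            for mod in self.modalities:
                if mod.name == m:
                    return mod
            raise KeyError(f"unknown modality {m!r}")
        return self.modalities[m]

    def factor(self, f: int | str) -> StateFactor:
        if isinstance(f, str):
            for fac in self.factors:
                if fac.name == f:
                    return fac
            raise KeyError(f"unknown factor {f!r}")
        return self.factors[f]

    def factor_marginal(self, joint: np.ndarray, f: int | str) -> np.ndarray:
        """Marginalise a joint-state distribution onto one factor."""
        if isinstance(f, str):
            f = [fac.name for fac in self.factors].index(f)
        grid = np.asarray(joint, dtype=float).reshape(self.factor_sizes)
        axes = tuple(i for i in range(len(self.factors)) if i != f)
        return grid.sum(axis=axes) if axes else grid

    def replace_factor(self, f: int | str, **changes) -> None:
        if isinstance(f, str):
            f = [fac.name for fac in self.factors].index(f)
        self.factors[f] = replace(self.factors[f], **changes)

    def replace_modality(self, m: int | str, **changes) -> None:
        if isinstance(m, str):
            m = [mod.name for mod in self.modalities].index(m)
        self.modalities[m] = replace(self.modalities[m], **changes)


def model_to_dict(model: GenerativeModel) -> dict:
    """Plain-data description of a model (lossless, YAML/JSON friendly)."""
    return {
        "horizon": int(model.horizon),
        "policies": model.policies.tolist(),
        "factors": [
            {
                "name": f.name,
                "d": f.d.values.tolist(),
                "d_learnable": bool(f.d.learnable),
                "B": f.B.tolist(),
            }
            for f in model.factors
        ],
        "modalities": [
            {
                "name": m.name,
                "a": m.a.values.tolist(),
                "a_learnable": bool(m.a.learnable),
                "preferences": None if m.preferences is None else m.preferences.tolist(),
            }
            for m in model.modalities
        ],
    }


def model_from_dict(data: dict) -> GenerativeModel:
    """Inverse of :func:`model_to_dict`."""
    factors = [
        StateFactor(
            f["name"],
            DirichletCounts(np.asarray(f["d"], dtype=float), learnable=f["d_learnable"]),
            np.asarray(f["B"], dtype=float),
        )
        for f in data["factors"]
    ]
    modalities = [
        Modality(
            m["name"],
            DirichletCounts(np.asarray(m["a"], dtype=float), learnable=m["a_learnable"]),
            preferences=None if m.get("preferences") is None else np.asarray(m["preferences"], dtype=float),
        )
        for m in data["modalities"]
    ]
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        policies=np.asarray(data["policies"], dtype=int),
        horizon=int(data["horizon"]),
    )


def save_model(model: GenerativeModel, path) -> None:
    """Write a model specification file (YAML); round-trips losslessly."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> GenerativeModel:
    import yaml

    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


@dataclass
class GenerativeProcess:
    """The environment: true likelihoods/transitions plus an outcome sampler.

    Shares category labels and structure with the paired generative model but
    carries its own parameters; no preferences, policies or learning.
    """

    factors: list[StateFactor]
    modalities: list[Modality]
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(f.n_states for f in self.factors)

    def modality(self, m: int | str) -> Modality:
        return GenerativeModel.modality(self, m)

    def factor(self, f: int | str) -> StateFactor:
        return GenerativeModel.factor(self, f)

    def initial_state(self) -> tuple[int, ...]:
        return tuple(int(self.rng.choice(f.n_states, p=f.prior())) for f in self.factors)

    def step(self, state: tuple[int, ...], actions) -> tuple[int, ...]:
        actions = np.broadcast_to(np.asarray(actions, dtype=int), (len(self.factors),))
        out = []
        for f, s, u in zip(self.factors, state, actions):
            out.append(int(self.rng.choice(f.n_states, p=f.B[:, s, u])))
        return tuple(out)

    def observe(self, state: tuple[int, ...]) -> list[int]:
        obs = []
        for mod in self.modalities:
            col = mod.a.normalized()[(slice(None), *state)]
            obs.append(int(self.rng.choice(mod.n_outcomes, p=col)))
        return obs


def one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v
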