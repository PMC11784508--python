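"""Action: expected-free-energy policy scoring and selection.

Each policy's expected free energy decomposes per timestep into

    G = risk + ambiguity - novelty

where risk is the KL-style divergence of predicted outcomes ``A s`` from
the softmax-normalised preferences ``C``, ambiguity is the expected
conditional outcome entropy, and novelty is the expected information gain
about the Dirichlet likelihood counts, weighted by

    W = 1/2 (a^(-1) - a_sums^(-1)).

The policy posterior is softmax(-gamma G): policies with lower expected
free energy are more probable.  Only modalities whose likelihood counts are
learnable contribute novelty; locked mappings generate no epistemic drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import BeliefState
from .model import DirichletCounts, GenerativeModel, softmax, stable_log

__all__ = [
    "PolicyEvaluation",
    "novelty_weight",
    "expected_free_energy",
    "policy_posterior",
    "select_action",
]


@dataclass
class PolicyEvaluation:
    """Expected free energy of one policy, decomposed per scored timestep."""

    policy: int
    G: float
    risk: np.ndarray
    ambiguity: np.ndarray
    novelty: np.ndarray
    predicted_outcomes: dict[str, np.ndarray] = field(default_factory=dict)
    timesteps: tuple[int, ...] = ()


def novelty_weight(counts: DirichletCounts | np.ndarray) -> np.ndarray:
    """Elementwise W = 1/2 (1/a - 1/column-sum-of-a), broadcast to a's shape."""
    a = counts.values if isinstance(counts, DirichletCounts) else np.asarray(counts, dtype=float)
    if np.any(a <= 0):
        raise ValueError("novelty weights require strictly positive counts")
    return 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))


def expected_free_energy(
    model: GenerativeModel,
    belief: BeliefState,
    policy: int | None = None,
    timesteps=None,
) -> PolicyEvaluation:
    """Score one policy's belief trajectory.

    ``timesteps`` selects which timesteps enter G (default: all); an
    experiment typically scores only future, unobserved timesteps, since
    already-observed ones add policy-independent constants.
    """
    if policy is None:
        policy = belief.policy
    s = np.atleast_2d(belief.s)
    if timesteps is None:
        timesteps = tuple(range(s.shape[0]))
    timesteps = tuple(int(t) for t in timesteps)

    risk = np.zeros(len(timesteps))
    ambiguity = np.zeros(len(timesteps))
    novelty = np.zeros(len(timesteps))
    predicted: dict[str, np.ndarray] = {}

    for m, mod in enumerate(model.modalities):
        A = model.joint_likelihood(m)
        lnA = stable_log(A)
        lnC = mod.log_preferences()  # raises if the modality has no preferences
        neg_entropy = np.einsum("oj,oj->j", A, lnA)  # diag(A^T ln A)
        W = None
        if mod.a.learnable:
            W = novelty_weight(mod.a).reshape(A.shape[0], -1)
        for k, t in enumerate(timesteps):
            o_pred = A @ s[t]
            risk[k] += o_pred @ (stable_log(o_pred) - lnC)
            ambiguity[k] += -(neg_entropy @ s[t])
            if W is not None:
                novelty[k] += o_pred @ (W @ s[t])
            predicted.setdefault(mod.name, np.zeros((len(timesteps), A.shape[0])))[k] = o_pred

    G = float(np.sum(risk + ambiguity - novelty))
    return PolicyEvaluation(
        policy=policy,
        G=G,
        risk=risk,
        ambiguity=ambiguity,
        novelty=novelty,
        predicted_outcomes=predicted,
        timesteps=timesteps,
    )


def policy_posterior(evaluations, precision: float = 1.0) -> np.ndarray:
    """Posterior over policies: softmax of -precision * G.

    Lower expected free energy means higher probability, consistent with
    selecting policies that minimise G.
    """
    if len(evaluations) < 1:
        raise ValueError("at least one policy evaluation is required")
    G = np.array([e.G if isinstance(e, PolicyEvaluation) else float(e) for e in evaluations])
    return softmax(-precision * G)


def select_action(posterior, mode: str = "sample", rng=None) -> int:
    """Draw or pick an action index from a policy posterior.

    ``sample`` draws from the posterior using ``rng`` (a seed or Generator);
    ``argmax`` is deterministic with a lowest-index tie-break.
    """
    p = np.asarray(posterior, dtype=float)
    if mode == "argmax":
        return int(np.argmax(p))
    if mode == "sample":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return int(rng.choice(p.shape[0], p=p / p.sum()))
    raise ValueError(f"unknown selection mode {mode!r}")
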