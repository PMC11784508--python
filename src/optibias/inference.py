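"""Perception: variational inference of hidden states per policy.

The approximate posterior ``s`` over the joint state space is found by
gradient descent on the marginal free energy

    F = s . (ln s - msg - ln A^T o)

where ``msg`` averages the transition messages present at a timestep: the
forward message ln(B s_prev) (the prior ln D at the first timestep) and the
backward message ln(B-dagger s_next).  When both exist each carries weight
1/2; a lone message carries full weight, which makes single-timestep
inference agree exactly with Bayes' rule.

The fixed-point iteration is the standard scheme

    eps <- ln A^T o + msg - ln s ;  v <- v + eps ;  s <- softmax(v)

with at most 16 sweeps.  Because softmax is shift-invariant, eps tends to a
constant vector (the log-normaliser) at the fixed point rather than to
zero, so eps is mean-centred before the v update and convergence is judged
on the centred residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenerativeModel, softmax, stable_log, transpose_normalized

__all__ = ["BeliefState", "infer_states", "marginal_free_energy"]

MAX_ITERATIONS = 16
CONVERGENCE_TOL = 1e-4


@dataclass
class BeliefState:
    """Per-policy posterior trajectory with the iteration's internals.

    ``s`` has shape (T, n_joint_states); ``v`` is the accumulated log-state
    vector with ``s = softmax(v)`` after every iteration; ``epsilon`` is the
    final (centred) prediction error; ``iterations`` counts sweeps run.
    """

    s: np.ndarray
    v: np.ndarray
    epsilon: np.ndarray
    iterations: int
    policy: int = 0


def _log_evidence(model: GenerativeModel, observations) -> np.ndarray:
    """Sum of ln A^T o across modalities for every timestep.

    ``observations`` is a sequence of length T; each entry is either None
    (fully unobserved timestep) or a sequence with one entry per modality,
    each a probability vector (one-hot or soft) or None.
    """
    T = len(observations)
    L = np.zeros((T, model.n_states))
    for t, obs_t in enumerate(observations):
        if obs_t is None:
            continue
        if len(obs_t) != len(model.modalities):
            raise ValueError(
                f"timestep {t}: expected {len(model.modalities)} modality observations, got {len(obs_t)}"
            )
        for m, o in enumerate(obs_t):
            if o is None:
                continue
            o = np.asarray(o, dtype=float)
            A = model.joint_likelihood(m)
            if o.shape[0] != A.shape[0]:
                raise ValueError(
                    f"timestep {t}, modality {model.modalities[m].name}: observation length "
                    f"{o.shape[0]} does not match {A.shape[0]} outcomes"
                )
            L[t] += stable_log(A).T @ o
    return L


def _transition_cache(model: GenerativeModel, policy: int, T: int):
    """Joint B and B-dagger for each transition step of one policy."""
    Bs = [model.joint_transition(policy, t) for t in range(1, T)]
    return Bs, [transpose_normalized(B) for B in Bs]


def _messages(model: GenerativeModel, s: np.ndarray, policy: int, cache=None, lnD=None) -> np.ndarray:
    """Averaged forward/backward transition messages for every timestep."""
    T, n = s.shape
    if lnD is None:
        lnD = stable_log(model.joint_prior())
    Bs, Bdags = cache if cache is not None else _transition_cache(model, policy, T)
    msg = np.zeros((T, n))
    for t in range(T):
        if t == 0:
            terms = [lnD]
        else:
            terms = [stable_log(Bs[t - 1] @ s[t - 1])]
        if t < T - 1:
            terms.append(stable_log(Bdags[t] @ s[t + 1]))
        msg[t] = terms[0] if len(terms) == 1 else 0.5 * (terms[0] + terms[1])
    return msg


def infer_states(
    model: GenerativeModel,
    observations,
    policy: int = 0,
    max_iterations: int = MAX_ITERATIONS,
    tol: float = CONVERGENCE_TOL,
) -> BeliefState:
    """Infer the posterior state trajectory under one policy.

    Observations may be one-hot or soft probability vectors; missing entries
    (None) contribute no evidence, so future timesteps carry pure
    transition-message predictions.  ``v`` is initialised to the log state
    prior.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    T = len(observations)
    if T < 1:
        raise ValueError("at least one timestep of observations is required")
    if model.n_policies <= policy:
        raise ValueError(f"model has no policy {policy}")
    if T > model.horizon:
        raise ValueError(f"{T} timesteps exceed the model horizon {model.horizon}")

    L = _log_evidence(model, observations)
    lnD = stable_log(model.joint_prior())
    cache = _transition_cache(model, policy, T)
    v = np.tile(lnD, (T, 1))
    s = softmax(v, axis=1)
    eps = np.zeros_like(v)
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        msg = _messages(model, s, policy, cache, lnD)
        eps = L + msg - stable_log(s)
        eps = eps - eps.mean(axis=1, keepdims=True)
        v = v + eps
        s_new = softmax(v, axis=1)
        # stop on a small centred residual or once the posterior is pinned
        # at the simplex boundary and no longer moves
        converged = np.max(np.abs(eps)) < tol or np.max(np.abs(s_new - s)) < 1e-9
        s = s_new
        if converged:
            break
    return BeliefState(s=s, v=v, epsilon=eps, iterations=iterations, policy=policy)


def marginal_free_energy(
    belief: BeliefState,
    model: GenerativeModel,
    observations,
    policy: int | None = None,
) -> np.ndarray:
    """Marginal free energy per timestep at the belief's current posterior.

    Evaluates s . (ln s - msg - ln A^T o) with the same message convention
    as the update scheme; finite for any posterior on the simplex and
    non-increasing (to tolerance) across inference iterations.
    """
    if policy is None:
        policy = belief.policy
    s = np.atleast_2d(belief.s)
    if len(observations) != s.shape[0]:
        raise ValueError("observation sequence length does not match belief trajectory")
    if s.shape[1] != model.n_states:
        raise ValueError("belief dimension does not match the model's joint state space")
    L = _log_evidence(model, observations)
    msg = _messages(model, s, policy)
    return np.einsum("ti,ti->t", s, stable_log(s) - msg - L)
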