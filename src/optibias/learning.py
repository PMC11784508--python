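"""Dirichlet concentration-parameter learning.

Likelihood counts accumulate the outer product of observation and state
posterior, summed over a trial's timesteps::

    a_{trial+1} = a_trial + sum_t o_t (x) s_t

and initial-state counts accumulate the first-timestep posterior::

    d_{trial+1} = d_trial + s_{tau=1}.

Both use the Bayesian model average over policies as the state posterior.
Because counts only grow, earlier observations shift the normalised
distribution more than later identical ones — learning slows as evidence
accumulates.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import DirichletCounts

__all__ = ["update_a", "update_d", "optimism_level"]


def update_a(counts: DirichletCounts, observations, state_posteriors) -> DirichletCounts:
    """Add sum_t o_t (x) s_t to likelihood counts.

    ``observations`` and ``state_posteriors`` are sequences (one entry per
    timestep) of probability vectors; the posterior is over the *joint*
    state configuration and is reshaped onto the table's conditioning axes.
    Each timestep adds total mass 1.  Locked blocks are left untouched with
    a warning.
    """
    if not counts.learnable:
        warnings.warn("update_a called on a locked Dirichlet block; no-op", stacklevel=2)
        return counts
    new = counts.values.copy()
    state_shape = counts.values.shape[1:]
    for o, s in zip(observations, state_posteriors, strict=True):
        o = np.asarray(o, dtype=float)
        s = np.asarray(s, dtype=float).reshape(state_shape)
        new += np.multiply.outer(o, s)
    return DirichletCounts(new, learnable=True)


def update_d(counts: DirichletCounts, first_state_posterior) -> DirichletCounts:
    """Add the tau=1 state posterior (mass 1) to initial-state counts."""
    if not counts.learnable:
        warnings.warn("update_d called on a locked Dirichlet block; no-op", stacklevel=2)
        return counts
    s = np.asarray(first_state_posterior, dtype=float)
    if s.shape != counts.values.shape:
        raise ValueError(f"posterior shape {s.shape} does not match d shape {counts.values.shape}")
    return DirichletCounts(counts.values + s, learnable=True)


def optimism_level(d: DirichletCounts | np.ndarray) -> float:
    """First (optimistic) entry of the normalised two-state optimism counts.

    Scale-invariant: counts [8, 2] and probabilities [0.8, 0.2] both give
    optimism level 0.8.
    """
    values = d.values if isinstance(d, DirichletCounts) else np.asarray(d, dtype=float)
    if values.shape != (2,):
        raise ValueError("the optimism factor must have exactly two states")
    total = values.sum()
    if total <= 0:
        raise ValueError("degenerate optimism counts")
    return float(values[0] / total)
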