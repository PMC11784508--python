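"""Independent reference implementations used as test oracles.

Everything here is written as direct, loop-based transcriptions of the
update equations and scoring formulas, deliberately sharing no code with
the package's vectorised implementations.
"""

import math

import numpy as np

EPS = 1e-16


def ln(x):
    return math.log(x + EPS)


def bayes_posterior(prior, A, obs_index):
    """Exact single-timestep Bayes rule by enumeration over states."""
    n = len(prior)
    joint = [prior[j] * A[obs_index][j] for j in range(n)]
    z = sum(joint)
    return np.array([j / z for j in joint])


def free_energy_reference(s_traj, prior, B_list, obs_loglik):
    """Direct evaluation of F per timestep.

    F_t = s_t . (ln s_t - msg_t - ln A^T o_t) with msg the average of the
    transition messages present: ln(prior) at t=0 (forward), ln(B_t s_{t-1})
    for t>0, and ln(Bdag_{t+1} s_{t+1}) when a successor exists.
    """
    T = len(s_traj)
    out = []
    for t in range(T):
        n = len(s_traj[t])
        terms = []
        if t == 0:
            terms.append([ln(p) for p in prior])
        else:
            pred = [sum(B_list[t - 1][i][j] * s_traj[t - 1][j] for j in range(n)) for i in range(n)]
            terms.append([ln(p) for p in pred])
        if t < T - 1:
            B = np.asarray(B_list[t], dtype=float)
            Bd = B.T.copy()
            for c in range(Bd.shape[1]):
                csum = Bd[:, c].sum()
                Bd[:, c] = 1.0 / Bd.shape[0] if csum <= 0 else Bd[:, c] / csum
            pred = [sum(Bd[i][j] * s_traj[t + 1][j] for j in range(n)) for i in range(n)]
            terms.append([ln(p) for p in pred])
        msg = [sum(term[i] for term in terms) / len(terms) for i in range(n)]
        F = sum(
            s_traj[t][i] * (ln(s_traj[t][i]) - msg[i] - obs_loglik[t][i]) for i in range(n)
        )
        out.append(F)
    return np.array(out)


def novelty_weight_reference(a):
    """W = 1/2 (1/a - 1/column_sums(a)), elementwise by loops."""
    a = np.asarray(a, dtype=float)
    flat = a.reshape(a.shape[0], -1)
    W = np.zeros_like(flat)
    for col in range(flat.shape[1]):
        csum = flat[:, col].sum()
        for row in range(flat.shape[0]):
            W[row, col] = 0.5 * (1.0 / flat[row, col] - 1.0 / csum)
    return W.reshape(a.shape)


def efe_reference(A, a_counts, s, lnC, learnable=True):
    """Single-timestep G = risk + ambiguity - novelty by explicit loops."""
    A = np.asarray(A, dtype=float)
    n_out, n_states = A.shape
    o_pred = [sum(A[o][j] * s[j] for j in range(n_states)) for o in range(n_out)]
    risk = sum(o_pred[o] * (ln(o_pred[o]) - lnC[o]) for o in range(n_out))
    ambiguity = -sum(
        s[j] * sum(A[o][j] * ln(A[o][j]) for o in range(n_out)) for j in range(n_states)
    )
    novelty = 0.0
    if learnable:
        W = novelty_weight_reference(a_counts).reshape(n_out, n_states)
        Ws = [sum(W[o][j] * s[j] for j in range(n_states)) for o in range(n_out)]
        novelty = sum(o_pred[o] * Ws[o] for o in range(n_out))
    return risk + ambiguity - novelty, risk, ambiguity, novelty


def update_a_reference(a, observations, posteriors):
    """a_{trial+1} = a_trial + sum_t o_t (x) s_t, by loops."""
    a = np.asarray(a, dtype=float).copy()
    flat = a.reshape(a.shape[0], -1)
    for o, s in zip(observations, posteriors):
        for i in range(flat.shape[0]):
            for j in range(flat.shape[1]):
                flat[i, j] += o[i] * s[j]
    return flat.reshape(a.shape)


def update_d_reference(d, s1):
    return np.asarray(d, dtype=float) + np.asarray(s1, dtype=float)
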