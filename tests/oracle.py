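"""Brute-force enumeration oracle for small categorical models.

Independent of the production inference path: the joint posterior over
whole state sequences is computed by explicit summation, then reduced to
per-factor, per-epoch marginals and the evidence Z.
"""
from __future__ import annotations

import itertools

import numpy as np

from actinfsim.model_spec import GenerativeModel


def enumerate_posterior(
    model: GenerativeModel,
    observations,
    actions,
):
    """Exact marginals and evidence by summing over all state sequences.

    Returns (marginals, Z) where marginals[f] has shape (t, n_levels_f).
    """
    obs = np.asarray(observations, dtype=np.int64)
    t = obs.shape[0]
    sizes = model.state_shape
    n_factors = len(sizes)
    states = list(itertools.product(*[range(s) for s in sizes]))

    Z = 0.0
    marg = [np.zeros((t, s)) for s in sizes]
    for seq in itertools.product(states, repeat=t):
        p = 1.0
        for f in range(n_factors):
            p *= model.D[f][seq[0][f]]
        for tau in range(1, t):
            a = actions[tau - 1]
            for f in range(n_factors):
                p *= model.B[f][a][seq[tau][f], seq[tau - 1][f]]
        for tau in range(t):
            for m in range(model.n_modalities):
                p *= model.A[m][(obs[tau, m], *seq[tau])]
        if p == 0.0:
            continue
        Z += p
        for tau in range(t):
            for f in range(n_factors):
                marg[f][tau, seq[tau][f]] += p
    if Z > 0:
        marg = [m / Z for m in marg]
    return marg, Z


def efe_brute_force(q_states, outcome_lik, C_dist):
    """Independent arithmetic oracle for a single modality and epoch.

    q_states: (n_states,) predicted state distribution.
    outcome_lik: (n_out, n_states) likelihood columns.
    C_dist: (n_out,) preference probabilities.
    Returns (risk, ambiguity) by direct summation.
    """
    q_states = np.asarray(q_states, dtype=float)
    L = np.asarray(outcome_lik, dtype=float)
    qo = L @ q_states
    risk = 0.0
    for o in range(L.shape[0]):
        if qo[o] > 0:
            risk += qo[o] * (np.log(qo[o]) - np.log(C_dist[o]))
    ambiguity = 0.0
    for s in range(L.shape[1]):
        h = 0.0
        for o in range(L.shape[0]):
            if L[o, s] > 0:
                h -= L[o, s] * np.log(L[o, s])
        ambiguity += q_states[s] * h
    return risk, ambiguity
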