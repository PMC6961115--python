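"""Expected free energy, policy posteriors, and action selection.

The expected free energy of a policy sums, over future epochs, a risk
term (KL divergence of predicted outcomes from the softmax-normalized
preferences C) and an ambiguity term (expected conditional entropy of
outcomes given states).  Policies are scored by ``ln E - gamma*G - F``
and normalized with a softmax; actions are drawn from the posterior
marginal over the actions the policies prescribe at the current step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, softmax

from .inference_engine import BeliefState, InferenceEngine, PolicyBeliefs
from .model_spec import GenerativeModel

__all__ = [
    "PolicyEvaluation",
    "EfeDecomposition",
    "expected_free_energy",
    "policy_posterior",
    "select_action",
    "NoAdmissiblePolicyError",
]


class NoAdmissiblePolicyError(ValueError):
    """All policies carry zero posterior probability."""


@dataclass
class EfeDecomposition:
    """Per-epoch risk / ambiguity for one policy; epochs are absolute."""

    epochs: np.ndarray  # (n_epochs,) absolute epoch indices (1-based)
    risk: np.ndarray
    ambiguity: np.ndarray

    @property
    def G(self) -> float:
        return float(self.risk.sum() + self.ambiguity.sum())


@dataclass
class PolicyEvaluation:
    """Scores for a whole policy set at one choice point."""

    G: np.ndarray  # (n_policies,)
    risk: np.ndarray  # (n_policies, n_epochs)
    ambiguity: np.ndarray  # (n_policies, n_epochs)
    F: np.ndarray  # (n_policies,)
    posterior: np.ndarray  # (n_policies,)
    gamma: float


def _preference_dists(model: GenerativeModel) -> list[np.ndarray]:
    return [softmax(c) for c in model.C]


def expected_free_energy(
    model: GenerativeModel,
    beliefs: PolicyBeliefs,
    policy=None,
    from_epoch: int | None = None,
    *,
    engine: InferenceEngine | None = None,
) -> EfeDecomposition:
    """Risk + ambiguity decomposition of G for one policy.

    from_epoch: first epoch (1-based) treated as future; defaults to the
    epoch after the last observed one.  Predicted state distributions are
    taken from the predictive rows of ``beliefs``.
    """
    if engine is None:
        engine = InferenceEngine(model)
    if from_epoch is None:
        from_epoch = beliefs.t_obs + 1
    taus = list(range(from_epoch - 1, model.horizon))
    C_dists = _preference_dists(model)
    risk = np.zeros(len(taus))
    ambiguity = np.zeros(len(taus))
    for k, tau in enumerate(taus):
        qs = [beliefs.q[f][tau] for f in range(model.n_factors)]
        joint = qs[0]
        for qv in qs[1:]:
            joint = np.multiply.outer(joint, qv)
        r = 0.0
        amb = 0.0
        for m in range(model.n_modalities):
            qo = np.tensordot(
                engine.A[m], joint, axes=(tuple(range(1, model.n_factors + 1)),
                                          tuple(range(model.n_factors))),
            )
            qo = np.maximum(qo, 0.0)
            s = qo.sum()
            if s > 0:
                qo = qo / s
            r += float(rel_entr(qo, C_dists[m]).sum())
            amb += float((engine.H_A[m] * joint).sum())
        risk[k] = r
        ambiguity[k] = amb
    return EfeDecomposition(
        epochs=np.array([tau + 1 for tau in taus]), risk=risk, ambiguity=ambiguity
    )


def policy_posterior(
    G: np.ndarray,
    F: np.ndarray,
    E: np.ndarray,
    gamma: float = 1.0,
) -> np.ndarray:
    """Softmax posterior over policies: sigma(ln E - gamma*G - F).

    ``+inf`` entries of F or G map to zero posterior probability.
    """
    G = np.asarray(G, dtype=float)
    F = np.asarray(F, dtype=float)
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore"):
        logits = np.log(np.where(E > 0, E, 0.0), where=E > 0,
                        out=np.full_like(E, -np.inf)) - gamma * G - F
    logits = np.where(np.isnan(logits), -np.inf, logits)
    finite = np.isfinite(logits)
    if not finite.any():
        raise NoAdmissiblePolicyError("every policy has zero posterior probability")
    out = np.zeros_like(logits)
    shifted = logits[finite] - logits[finite].max()
    w = np.exp(shifted)
    out[finite] = w / w.sum()
    return out


def evaluate_policies(
    model: GenerativeModel,
    belief_state: BeliefState,
    *,
    gamma: float = 1.0,
    engine: InferenceEngine | None = None,
) -> PolicyEvaluation:
    """Score every policy (G decomposition, posterior) at a choice point."""
    if engine is None:
        engine = InferenceEngine(model)
    decomps = [
        expected_free_energy(model, pb, engine=engine)
        for pb in belief_state.per_policy
    ]
    n_ep = max((d.risk.size for d in decomps), default=0)
    risk = np.zeros((len(decomps), n_ep))
    amb = np.zeros((len(decomps), n_ep))
    for p, d in enumerate(decomps):
        risk[p, : d.risk.size] = d.risk
        amb[p, : d.ambiguity.size] = d.ambiguity
    G = risk.sum(axis=1) + amb.sum(axis=1)
    F = belief_state.F
    post = policy_posterior(G, F, model.policies.E, gamma)
    return PolicyEvaluation(G=G, risk=risk, ambiguity=amb, F=F, posterior=post,
                            gamma=gamma)


def action_marginal(
    posterior: np.ndarray, U: np.ndarray, step: int, n_actions: int = 4
) -> np.ndarray:
    """Posterior mass grouped by the action each policy prescribes."""
    if not (0 <= step < U.shape[0]):
        raise ValueError(f"step {step} outside action range 0..{U.shape[0] - 1}")
    marg = np.zeros(n_actions)
    np.add.at(marg, U[step], posterior)
    s = marg.sum()
    if s > 0:
        marg /= s
    return marg


def select_action(
    posterior: np.ndarray,
    U: np.ndarray,
    step: int,
    mode: str = "sample",
    rng: np.random.Generator | int | None = None,
    n_actions: int = 4,
) -> int:
    """Select the action at ``step`` (0-based) from the policy posterior.

    mode="argmax" picks the modal action (ties -> lowest index);
    mode="sample" draws from the marginal with the given generator/seed.
    """
    marg = action_marginal(posterior, U, step, n_actions)
    if mode == "argmax":
        return int(np.argmax(marg))
    if mode != "sample":
        raise ValueError(f"unknown action mode {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return int(rng.choice(n_actions, p=marg))
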