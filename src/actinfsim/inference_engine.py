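"""Per-policy posterior state estimation and variational free energy.

State estimation runs damped fixed-point message passing on the factor
graph spanned by the observed epochs of a trial: each hidden-state factor
contributes a Markov chain (prior D, action-conditioned transitions B),
and each observed outcome contributes a likelihood factor that couples
the state factors it depends on.  Beliefs are the softmax of the summed
log-messages (likelihood, forward through B, backward from the next
epoch).  Epochs beyond the last observation are predictive and obtained
by pure forward propagation through the policy-conditioned transitions.

Zero probabilities in the model are floored (default exp(-16), matching
common practice for categorical MDP schemes) so that off-policy
observation sequences yield large-but-finite free energies rather than
numerical failure; pass ``floor=0`` for exact arithmetic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .model_spec import GenerativeModel

__all__ = [
    "PolicyBeliefs",
    "BpRaw",
    "BeliefState",
    "InferenceEngine",
    "infer_states",
    "variational_free_energy",
    "DEFAULT_FLOOR",
]

DEFAULT_FLOOR = math.exp(-16.0)


@dataclass
class PolicyBeliefs:
    """Posterior beliefs for a single policy.

    q[f] is an array (horizon, n_levels_f); rows 0..t_obs-1 are posterior
    over observed epochs, later rows are predictive.  iterate_log[f], when
    recorded, has shape (n_log, horizon, n_levels_f) with the final entry
    equal to q[f].
    """

    q: list[np.ndarray]
    F: float
    converged: bool
    n_sweeps: int
    t_obs: int
    actions: tuple[int, ...]
    iterate_log: list[np.ndarray] | None = None


@dataclass
class BpRaw:
    """Converged message-passing state for one observation/action prefix."""

    beliefs: list  # [tau][f] -> marginal over observed epochs
    t_obs: int
    prefix: tuple[int, ...]
    F: float
    converged: bool
    n_sweeps: int
    sweep_log: list | None = None
    msg_state: dict | None = None


@dataclass
class BeliefState:
    """Beliefs for every policy of a policy set, plus their free energies."""

    per_policy: list[PolicyBeliefs]

    @property
    def F(self) -> np.ndarray:
        return np.array([pb.F for pb in self.per_policy])

    @property
    def converged(self) -> bool:
        return all(pb.converged for pb in self.per_policy)


def _floor_norm(arr: np.ndarray, floor: float, axis: int = 0) -> np.ndarray:
    """Clip probabilities from below and renormalize along ``axis``."""
    if floor <= 0.0 or arr.min() >= floor:
        return arr
    out = np.maximum(arr, floor)
    return out / out.sum(axis=axis, keepdims=True)


class InferenceEngine:
    """Reusable inference machinery bound to one generative model.

    Precomputes floored likelihood/transition/prior arrays, their logs,
    modality scopes (which factors each modality actually depends on) and
    per-state outcome entropies (used by the policy engine).
    """

    def __init__(
        self,
        model: GenerativeModel,
        *,
        tol: float = 1e-6,
        max_iter: int = 64,
        damping: float = 0.5,
        floor: float = DEFAULT_FLOOR,
        n_log: int = 16,
    ) -> None:
        self.model = model
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.damping = float(damping)
        self.floor = float(floor)
        self.n_log = int(n_log)

        self.n_factors = model.n_factors
        self.n_modalities = model.n_modalities
        self.horizon = model.horizon
        self.state_shape = model.state_shape

        self.A = [_floor_norm(a, floor, axis=0) for a in model.A]
        self.B = [
            np.stack([_floor_norm(b[a], floor, axis=0) for a in range(b.shape[0])])
            for b in model.B
        ]
        self.D = [_floor_norm(d, floor, axis=0) for d in model.D]

        with np.errstate(divide="ignore"):
            self.lnA = [np.log(a) for a in self.A]
            self.lnB = [np.log(b) for b in self.B]
            self.lnD = [np.log(d) for d in self.D]

        # modality scopes: axes of A along which the likelihood varies
        self.scopes: list[tuple[int, ...]] = []
        self.A_red: list[np.ndarray] = []
        self.lnA_red: list[np.ndarray] = []
        for m, a in enumerate(self.A):
            scope = tuple(
                f
                for f in range(self.n_factors)
                if np.ptp(a, axis=f + 1).max() > 0.0
            )
            if not scope:  # totally uninformative modality: keep one axis
                scope = (0,)
            idx = tuple(
                slice(None) if (f in scope) else 0 for f in range(self.n_factors)
            )
            self.scopes.append(scope)
            self.A_red.append(a[(slice(None), *idx)])
            with np.errstate(divide="ignore"):
                self.lnA_red.append(np.log(self.A_red[-1]))

        # per-state outcome entropy H[m](s) = -sum_o A ln A (policy engine)
        self.H_A = [
            -np.sum(xlogy(a, a), axis=0) for a in self.A
        ]

    # ------------------------------------------------------------------
    # message passing
    # ------------------------------------------------------------------

    def infer(
        self,
        observations: Sequence[Sequence[int]],
        actions: Sequence[int],
        *,
        log_iterates: bool = False,
    ) -> PolicyBeliefs:
        """Infer per-factor posteriors under one policy.

        observations: outcome indices, shape (t_obs, n_modalities).
        actions: the policy's action indices (one per transition step).
        """
        actions = tuple(int(a) for a in actions)
        if len(actions) < self.horizon - 1:
            raise ValueError("policy must supply an action for every step")
        t = np.asarray(observations).shape[0]
        raw = self.run_bp(observations, actions[: t - 1], track_log=log_iterates)
        return self.beliefs_for_policy(raw, actions, log_iterates=log_iterates)

    def run_bp(
        self,
        observations: Sequence[Sequence[int]],
        prefix_actions: Sequence[int],
        *,
        track_log: bool = False,
        warm_start: "BpRaw | None" = None,
    ) -> "BpRaw":
        """Run the fixed-point scheme over the observed epochs only.

        The result depends only on the action prefix u_1..u_{t-1}, so it
        can be shared by every policy with that prefix.  ``warm_start``
        may supply the converged message state of the same trial at an
        earlier epoch (its prefix must be a prefix of this one).

        Messages are stored stacked over epochs: for each factor f,
        fwd[f] and bwd[f] are (t, n_f) arrays (fwd row 0 holds the prior
        D, bwd row t-1 is flat), and like[m][f] is a (t, n_f) array for
        each factor in modality m's scope.
        """
        obs = np.asarray(observations, dtype=np.int64)
        if obs.ndim != 2 or obs.shape[1] != self.n_modalities:
            raise ValueError("observations must have shape (t, n_modalities)")
        t = obs.shape[0]
        if not (1 <= t <= self.horizon):
            raise ValueError(f"need 1..{self.horizon} observed epochs, got {t}")
        for m in range(self.n_modalities):
            if obs[:, m].min() < 0 or obs[:, m].max() >= self.model.modalities[m].n:
                raise ValueError(f"observation index out of range for modality {m}")
        actions = tuple(int(a) for a in prefix_actions)
        if len(actions) < t - 1:
            raise ValueError("need an action for every observed transition")

        nF = self.n_factors
        sizes = self.state_shape
        lik = [self.A_red[m][obs[:, m]] for m in range(self.n_modalities)]
        # per-factor stacked transition matrices for steps 1..t-1
        Bu = [
            np.stack([self.B[f][actions[tau]] for tau in range(t - 1)])
            if t > 1
            else np.empty((0, sizes[f], sizes[f]))
            for f in range(nF)
        ]

        def flat(n: int, rows: int) -> np.ndarray:
            return np.full((rows, n), 1.0 / n)

        fwd = [flat(sizes[f], t) for f in range(nF)]
        bwd = [flat(sizes[f], t) for f in range(nF)]
        like = [
            {f: flat(sizes[f], t) for f in self.scopes[m]}
            for m in range(self.n_modalities)
        ]
        if warm_start is not None and warm_start.msg_state is not None:
            w = warm_start.msg_state
            t0 = warm_start.t_obs
            if t0 <= t and warm_start.prefix == actions[: t0 - 1]:
                for f in range(nF):
                    fwd[f][:t0] = w["fwd"][f]
                    if t0 > 1:
                        bwd[f][: t0 - 1] = w["bwd"][f][: t0 - 1]
                for m in range(self.n_modalities):
                    for f in self.scopes[m]:
                        like[m][f][:t0] = w["like"][m][f]
        for f in range(nF):
            fwd[f][0] = self.D[f]

        def norm_rows(arr: np.ndarray) -> np.ndarray:
            s = arr.sum(axis=1, keepdims=True)
            bad = s[:, 0] <= 0.0
            if bad.any():
                arr = arr.copy()
                arr[bad] = 1.0 / arr.shape[1]
                s = arr.sum(axis=1, keepdims=True)
            return arr / s

        def damp_rows(old: np.ndarray, new: np.ndarray) -> np.ndarray:
            new = norm_rows(new)
            if self.damping > 0.0:
                mixed = old**self.damping * new ** (1.0 - self.damping)
                return norm_rows(mixed)
            return new

        def belief_arrays() -> list[np.ndarray]:
            out = []
            for f in range(nF):
                prod = fwd[f] * bwd[f]
                for m in range(self.n_modalities):
                    if f in self.scopes[m]:
                        prod = prod * like[m][f]
                out.append(norm_rows(prod))
            return out

        def cavity(f: int, exclude: tuple) -> np.ndarray:
            """Product of incoming messages at factor f except one slot."""
            kind = exclude[0]
            prod = None
            if kind != "fwd":
                prod = fwd[f]
            if kind != "bwd":
                prod = bwd[f] if prod is None else prod * bwd[f]
            skip_m = exclude[1] if kind == "like" else None
            for m in range(self.n_modalities):
                if f in self.scopes[m] and m != skip_m:
                    prod = like[m][f] if prod is None else prod * like[m][f]
            return norm_rows(prod)

        beliefs_arr = belief_arrays()
        log: list = []
        converged = False
        sweeps = 0
        for sweep in range(self.max_iter):
            sweeps = sweep + 1
            for m in range(self.n_modalities):
                scope = self.scopes[m]
                if len(scope) == 1:
                    f = scope[0]
                    like[m][f] = damp_rows(like[m][f], lik[m])
                    continue
                cavs = {g: cavity(g, ("like", m)) for g in scope}
                for i, f in enumerate(scope):
                    T = lik[m]
                    # contract every other scope axis with its cavity
                    for j in range(len(scope) - 1, -1, -1):
                        if j == i:
                            continue
                        T = np.einsum(
                            T,
                            [0, *range(1, T.ndim)],
                            cavs[scope[j]],
                            [0, j + 1],
                            [0, *(k for k in range(1, T.ndim) if k != j + 1)],
                        )
                    like[m][f] = damp_rows(like[m][f], T)
            if t > 1:
                for f in range(nF):
                    cav = cavity(f, ("bwd",))
                    new = np.einsum("tij,tj->ti", Bu[f], cav[:-1])
                    fwd[f] = fwd[f].copy()
                    fwd[f][1:] = damp_rows(fwd[f][1:], new)
                    cav = cavity(f, ("fwd",))
                    new = np.einsum("tij,ti->tj", Bu[f], cav[1:])
                    bwd[f] = bwd[f].copy()
                    bwd[f][:-1] = damp_rows(bwd[f][:-1], new)

            new_beliefs = belief_arrays()
            delta = max(
                float(np.abs(new_beliefs[f] - beliefs_arr[f]).max())
                for f in range(nF)
            )
            beliefs_arr = new_beliefs
            if track_log:
                log.append(
                    [
                        [beliefs_arr[f][tau] for f in range(nF)]
                        for tau in range(t)
                    ]
                )
            if delta < self.tol:
                converged = True
                break

        beliefs = [[beliefs_arr[f][tau] for f in range(nF)] for tau in range(t)]
        F = self._free_energy(beliefs, obs, actions, t)
        return BpRaw(
            beliefs=beliefs,
            t_obs=t,
            prefix=actions[: t - 1],
            F=F,
            converged=converged,
            n_sweeps=sweeps,
            sweep_log=log if track_log else None,
            msg_state={"fwd": fwd, "bwd": bwd, "like": like},
        )

    def beliefs_for_policy(
        self,
        raw: "BpRaw",
        actions: Sequence[int],
        *,
        log_iterates: bool = False,
    ) -> PolicyBeliefs:
        """Extend a shared message-passing result with a policy's future."""
        actions = tuple(int(a) for a in actions)
        if len(actions) < self.horizon - 1:
            raise ValueError("policy must supply an action for every step")
        t = raw.t_obs
        if actions[: t - 1] != raw.prefix[: t - 1]:
            raise ValueError("policy does not share the inferred action prefix")
        q_full = self._full_beliefs(raw.beliefs, actions, t)
        q = [
            np.stack([q_full[tau][f] for tau in range(self.horizon)])
            for f in range(self.n_factors)
        ]
        iterate_log = None
        if log_iterates:
            if raw.sweep_log is None:
                raise ValueError("run_bp was called without track_log=True")
            log = [
                self._full_beliefs(snapshot, actions, t)
                for snapshot in raw.sweep_log
            ]
            iterate_log = self._pack_log(log, q)
        return PolicyBeliefs(
            q=q,
            F=raw.F,
            converged=raw.converged,
            n_sweeps=raw.n_sweeps,
            t_obs=t,
            actions=actions,
            iterate_log=iterate_log,
        )

    def _full_beliefs(self, beliefs, actions, t):
        """Observed-epoch beliefs plus predictive forward propagation."""
        full = [[beliefs[tau][f] for f in range(self.n_factors)] for tau in range(t)]
        cur = [beliefs[t - 1][f] for f in range(self.n_factors)]
        for tau in range(t, self.horizon):
            a = actions[tau - 1]
            cur = [self.B[f][a] @ cur[f] for f in range(self.n_factors)]
            full.append(list(cur))
        return full

    def _pack_log(self, log, q):
        """Pad / truncate the sweep log to exactly n_log entries per epoch."""
        n_log = self.n_log
        if len(log) >= n_log:
            entries = log[: n_log - 1] + [log[-1]]
        else:
            entries = log + [log[-1]] * (n_log - len(log))
        out = []
        for f in range(self.n_factors):
            arr = np.stack(
                [
                    np.stack([entry[tau][f] for tau in range(self.horizon)])
                    for entry in entries
                ]
            )
            arr[-1] = q[f]
            out.append(arr)
        return out

    # ------------------------------------------------------------------
    # free energy
    # ------------------------------------------------------------------

    def _free_energy(self, beliefs, obs, actions, t) -> float:
        lik_ln = [
            [self.lnA_red[m][obs[tau, m]] for m in range(self.n_modalities)]
            for tau in range(t)
        ]
        return _mean_field_F(
            beliefs,
            lik_ln,
            [(m, self.scopes[m]) for m in range(self.n_modalities)],
            self.lnB,
            self.lnD,
            actions,
            t,
            self.n_factors,
        )


def _expect_ln(T: np.ndarray, qs: list[np.ndarray]) -> float:
    """E[ln term] of tensor T under a product of marginals; +inf aware."""
    w = qs[0]
    for qv in qs[1:]:
        w = np.multiply.outer(w, qv)
    if np.any((w > 0) & ~np.isfinite(T)):
        return -math.inf
    return float(np.sum(np.where(w > 0, w * np.where(np.isfinite(T), T, 0.0), 0.0)))


def _mean_field_F(beliefs, lik_ln, scopes, lnB, lnD, actions, t, n_factors) -> float:
    F = 0.0
    for f in range(n_factors):
        for tau in range(t):
            q = beliefs[tau][f]
            F += float(xlogy(q, q).sum())
        term = _expect_ln(lnD[f], [beliefs[0][f]])
        if term == -math.inf:
            return math.inf
        F -= term
        for tau in range(1, t):
            a = actions[tau - 1]
            # E_{q_tau (x) q_{tau-1}}[ln B[to, from]]
            term = _expect_ln(lnB[f][a], [beliefs[tau][f], beliefs[tau - 1][f]])
            if term == -math.inf:
                return math.inf
            F -= term
    for tau in range(t):
        for m, scope in scopes:
            qs = [beliefs[tau][f] for f in scope]
            term = _expect_ln(lik_ln[tau][m], qs)
            if term == -math.inf:
                return math.inf
            F -= term
    return F


# ---------------------------------------------------------------------------
# public functional API
# ---------------------------------------------------------------------------


def infer_states(
    model: GenerativeModel,
    observations: Sequence[Sequence[int]],
    policy: Sequence[int],
    *,
    tol: float = 1e-6,
    max_iter: int = 64,
    damping: float = 0.5,
    floor: float = DEFAULT_FLOOR,
    log_iterates: bool = False,
) -> PolicyBeliefs:
    """One-shot convenience wrapper around :class:`InferenceEngine`."""
    engine = InferenceEngine(
        model, tol=tol, max_iter=max_iter, damping=damping, floor=floor
    )
    return engine.infer(observations, policy, log_iterates=log_iterates)


def variational_free_energy(
    model: GenerativeModel,
    observations: Sequence[Sequence[int]],
    Q: Sequence[np.ndarray],
    policy: Sequence[int],
    *,
    floor: float = 0.0,
) -> float:
    """Mean-field variational free energy of beliefs Q for a policy.

    Q[f] is an array (>= t_obs, n_levels_f) of per-epoch marginals.
    Observation sequences that are impossible under the (un-floored)
    model return ``+inf``.
    """
    obs = np.asarray(observations, dtype=np.int64)
    t = obs.shape[0]
    actions = tuple(int(a) for a in policy)
    engine = InferenceEngine(model, floor=floor)
    beliefs = [[np.asarray(Q[f][tau], dtype=float) for f in range(model.n_factors)]
               for tau in range(t)]
    for tau in range(t):
        for f in range(model.n_factors):
            s = beliefs[tau][f].sum()
            if not math.isclose(s, 1.0, abs_tol=1e-8):
                raise ValueError(f"Q[{f}][{tau}] is not normalized (sum={s})")
    lik_ln = [
        [engine.lnA_red[m][obs[tau, m]] for m in range(model.n_modalities)]
        for tau in range(t)
    ]
    return _mean_field_F(
        beliefs,
        lik_ln,
        [(m, engine.scopes[m]) for m in range(model.n_modalities)],
        engine.lnB,
        engine.lnD,
        actions,
        t,
        model.n_factors,
    )
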