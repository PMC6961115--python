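"""Simulated experiments: trial loop, grid runs, and phenotype metrics.

A trial runs the perceive-evaluate-act loop for six observation epochs
and five interleaved actions; an experiment cell repeats that for n
seeded trials under one (scenario, variant, condition) combination; the
summary derives policy-selection counts, defensive frequencies,
hard-freeze fold changes and relaxed-resumption contrasts with bootstrap
percentile intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference_engine import BeliefState, InferenceEngine
from .model_spec import (
    FIGHT_FLIGHT,
    FREEZE,
    N_POLICIES,
    GenerativeModel,
    ModelConfig,
    build_jerry_model,
    variant_config,
)
from .neural_responses import DEFAULT_DT, LfpTrace, simulate_lfp
from .policy_engine import evaluate_policies, select_action
from .world import SCENARIOS, World, Scenario

__all__ = [
    "VARIANTS",
    "Variant",
    "TrialTrace",
    "ExperimentCell",
    "ExperimentSummary",
    "run_trial",
    "run_experiment",
    "run_grid",
    "summarize",
    "DEFENSIVE_POLICIES",
    "HARD_FREEZE_POLICY",
    "RELAXED_RESUMPTION_POLICIES",
]


@dataclass(frozen=True)
class Variant:
    id: str
    lesioned: bool
    context: str


VARIANTS: dict[str, Variant] = {
    "I": Variant("I", lesioned=False, context="safe"),
    "II": Variant("II", lesioned=False, context="unsafe"),
    "III": Variant("III", lesioned=True, context="safe"),
    "IV": Variant("IV", lesioned=True, context="unsafe"),
}

#: 0-based indices of policies containing fight-or-flight or freeze.
DEFENSIVE_POLICIES = (0, 1, 2, 3, 4, 5)
#: the unrelenting freeze policy (P4).
HARD_FREEZE_POLICY = 3
#: policies whose final action is roaming/scanning (defences lowered).
RELAXED_RESUMPTION_POLICIES = (2, 5, 6)


@dataclass
class TrialTrace:
    """Everything recorded for a single trial."""

    scenario: str
    variant: str
    condition: str
    seed: int
    true_states: np.ndarray  # (horizon, n_factors)
    observations: np.ndarray  # (horizon, n_modalities)
    actions: np.ndarray  # (horizon - 1,)
    F: np.ndarray  # (horizon, n_policies)
    G: np.ndarray  # (horizon, n_policies)
    risk: np.ndarray  # (horizon, n_policies)
    ambiguity: np.ndarray  # (horizon, n_policies)
    policy_posterior: np.ndarray  # (horizon, n_policies)
    posterior_entropy: np.ndarray  # (horizon,)
    selected_policy: int  # 0-based
    beliefs: list[np.ndarray] = field(default_factory=list)  # BMA, [f](horizon, n_f)
    lfp: LfpTrace | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return self.observations.shape[0]


@dataclass
class ExperimentCell:
    scenario: str
    variant: str
    condition: str
    n_trials: int
    seed: int
    selections: np.ndarray  # (n_trials,) 0-based selected policy per trial

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.selections, minlength=N_POLICIES)

    def metric_counts(self) -> dict:
        sel = self.selections
        return {
            "defensive_count": int(np.isin(sel, DEFENSIVE_POLICIES).sum()),
            "defensive_frequency": float(np.isin(sel, DEFENSIVE_POLICIES).mean()),
            "hard_freeze_count": int((sel == HARD_FREEZE_POLICY).sum()),
            "relaxed_resumption_count": int(
                np.isin(sel, RELAXED_RESUMPTION_POLICIES).sum()
            ),
        }


def _entropy_of(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def run_trial(
    variant: str,
    scenario: str | Scenario,
    condition: str,
    seed: int | np.random.SeedSequence = 0,
    *,
    free_params: Mapping | None = None,
    gamma: float = 1.0,
    action_mode: str = "sample",
    tally_rule: str = "final",
    record_lfp: bool = False,
    dt: float = DEFAULT_DT,
    scripted_env: Sequence[int] | None = None,
    scripted_outcomes: Mapping[int, tuple] | None = None,
    model: GenerativeModel | None = None,
    engine: InferenceEngine | None = None,
    world: World | None = None,
    engine_kwargs: Mapping | None = None,
) -> TrialTrace:
    """Run one six-epoch trial of the perceive-evaluate-act loop.

    variant: "I".."IV" (lesion x context); scenario/condition pick the
    true initial creatures level and the clamped epoch-1 outcomes.
    Prebuilt model/engine/world may be supplied to amortise setup across
    trials; they must agree with variant and free_params when given.
    """
    scen = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    fp = dict(free_params or {})
    if model is None:
        model = build_jerry_model(variant_config(variant, **fp))
    if engine is None:
        engine = InferenceEngine(model, **dict(engine_kwargs or {}))
    if world is None:
        world = World(
            ModelConfig(**fp),
            scripted_env=scripted_env,
            scripted_outcomes=dict(scripted_outcomes or {}),
        )

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
        seed_label = int(ss.generate_state(1)[0])
    else:
        ss = np.random.SeedSequence(entropy=int(seed))
        seed_label = int(seed)
    ss_world, ss_action = ss.spawn(2)
    rng_world = np.random.default_rng(ss_world)
    rng_action = np.random.default_rng(ss_action)

    horizon = model.horizon
    U = model.policies.U
    n_pol = U.shape[1]

    state, outcomes = world.init_trial(scen, condition)
    true_states = [state.as_tuple()]
    observations = [tuple(outcomes)]
    actions: list[int] = []

    F = np.zeros((horizon, n_pol))
    G = np.zeros((horizon, n_pol))
    risk = np.zeros((horizon, n_pol))
    ambiguity = np.zeros((horizon, n_pol))
    posteriors = np.zeros((horizon, n_pol))
    entropies = np.zeros(horizon)
    warnings_list: list[str] = []
    lfp_slabs: list[np.ndarray] = []
    final_bma: list[np.ndarray] | None = None

    prev_cache: dict[tuple, object] = {}
    for t in range(1, horizon + 1):
        obs_arr = np.asarray(observations, dtype=np.int64)
        bp_cache: dict[tuple, object] = {}
        per_policy = []
        for p in range(n_pol):
            prefix = tuple(int(a) for a in U[: t - 1, p])
            if prefix not in bp_cache:
                donor = prev_cache.get(prefix[: t - 2]) if t > 1 else None
                bp_cache[prefix] = engine.run_bp(
                    obs_arr, prefix, track_log=record_lfp, warm_start=donor
                )
            raw = bp_cache[prefix]
            pb = engine.beliefs_for_policy(
                raw, tuple(int(a) for a in U[:, p]), log_iterates=record_lfp
            )
            if not pb.converged:
                warnings_list.append(
                    f"epoch {t}: inference for policy {p + 1} did not converge "
                    f"within {engine.max_iter} sweeps"
                )
            per_policy.append(pb)
        bs = BeliefState(per_policy)
        ev = evaluate_policies(model, bs, gamma=gamma, engine=engine)
        F[t - 1] = ev.F
        G[t - 1] = ev.G
        risk[t - 1] = ev.risk.sum(axis=1)
        ambiguity[t - 1] = ev.ambiguity.sum(axis=1)
        posteriors[t - 1] = ev.posterior
        entropies[t - 1] = _entropy_of(ev.posterior)

        if record_lfp:
            slab = _bma_iterates(per_policy, ev.posterior, engine)
            lfp_slabs.append(slab)
        if t == horizon:
            final_bma = _bma_final(per_policy, ev.posterior, engine)
        prev_cache = bp_cache

        if t < horizon:
            a = select_action(ev.posterior, U, t - 1, mode=action_mode,
                              rng=rng_action)
            actions.append(a)
            state = world.step_world(state, a, rng_world, epoch=t)
            outcomes = world.emit_outcomes(state, rng_world, epoch=t)
            true_states.append(state.as_tuple())
            observations.append(tuple(outcomes))

    selected = _tally(posteriors, np.asarray(actions), U, tally_rule)

    lfp = None
    if record_lfp:
        stacked = np.concatenate(lfp_slabs, axis=0)
        labels = _unit_labels(model)
        lfp = simulate_lfp(stacked, dt, unit_labels=labels,
                           iterates_per_epoch=engine.n_log)

    return TrialTrace(
        scenario=scen.id,
        variant=variant,
        condition=condition,
        seed=seed_label,
        true_states=np.asarray(true_states, dtype=np.int64),
        observations=np.asarray(observations, dtype=np.int64),
        actions=np.asarray(actions, dtype=np.int64),
        F=F,
        G=G,
        risk=risk,
        ambiguity=ambiguity,
        policy_posterior=posteriors,
        posterior_entropy=entropies,
        selected_policy=int(selected),
        beliefs=final_bma or [],
        lfp=lfp,
        warnings=warnings_list,
    )


def _tally(posteriors, actions, U, rule: str) -> int:
    if rule == "final":
        return int(np.argmax(posteriors[-1]))
    if rule == "first-defensive":
        for step, a in enumerate(actions):
            if a in (FIGHT_FLIGHT, FREEZE):
                return int(np.argmax(posteriors[step + 1]))
        return int(np.argmax(posteriors[-1]))
    raise ValueError(f"unknown tally rule {rule!r}")


def _bma_iterates(per_policy, posterior, engine) -> np.ndarray:
    """Policy-averaged belief iterates, flattened to (n_log, n_units)."""
    n_log = engine.n_log
    horizon = engine.horizon
    cols = []
    for f in range(engine.n_factors):
        acc = np.zeros_like(per_policy[0].iterate_log[f])
        for w, pb in zip(posterior, per_policy):
            if w > 0:
                acc += w * pb.iterate_log[f]
        cols.append(acc.reshape(n_log, horizon * acc.shape[2]))
    return np.concatenate(cols, axis=1)


def _bma_final(per_policy, posterior, engine) -> list[np.ndarray]:
    out = []
    for f in range(engine.n_factors):
        acc = np.zeros_like(per_policy[0].q[f])
        for w, pb in zip(posterior, per_policy):
            if w > 0:
                acc += w * pb.q[f]
        out.append(acc)
    return out


def _unit_labels(model: GenerativeModel) -> list[str]:
    labels = []
    for f in model.factors:
        for tau in range(model.horizon):
            for lvl in f.levels:
                labels.append(f"{f.name}[{lvl}]@t{tau + 1}")
    return labels


# ---------------------------------------------------------------------------
# experiment grids
# ---------------------------------------------------------------------------


def run_experiment(
    scenario: str,
    variant: str,
    condition: str,
    n_trials: int = 32,
    seed: int = 0,
    **trial_kwargs,
) -> ExperimentCell:
    """Run one cell: independent seeded trials, tally selected policies."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    fp = dict(trial_kwargs.pop("free_params", None) or {})
    model = trial_kwargs.pop("model", None) or build_jerry_model(
        variant_config(variant, **fp)
    )
    engine = trial_kwargs.pop("engine", None) or InferenceEngine(
        model, **dict(trial_kwargs.pop("engine_kwargs", None) or {})
    )
    world = trial_kwargs.pop("world", None) or World(ModelConfig(**fp))

    # the variant is deliberately left out of the entropy so that lesion /
    # context contrasts are paired on the same world randomness
    scen_i = sorted(SCENARIOS).index(scenario)
    cond_i = sorted(SCENARIOS[scenario].conditions).index(condition)
    cell_ss = np.random.SeedSequence(entropy=(int(seed), scen_i, cond_i))
    trial_seeds = cell_ss.spawn(n_trials)

    selections = np.empty(n_trials, dtype=np.int64)
    for i in range(n_trials):
        trace = run_trial(
            variant,
            scenario,
            condition,
            trial_seeds[i],
            free_params=fp,
            model=model,
            engine=engine,
            world=world,
            **trial_kwargs,
        )
        selections[i] = trace.selected_policy
    return ExperimentCell(
        scenario=scenario,
        variant=variant,
        condition=condition,
        n_trials=n_trials,
        seed=int(seed),
        selections=selections,
    )


def run_grid(
    scenarios: Sequence[str] = ("scenario1", "scenario2"),
    variants: Sequence[str] = ("I", "II", "III", "IV"),
    n_trials: int = 32,
    seed: int = 0,
    **trial_kwargs,
) -> dict[tuple[str, str, str], ExperimentCell]:
    """The full variants x conditions grid for the given scenarios."""
    cells = {}
    for scenario in scenarios:
        for variant in variants:
            for condition in sorted(SCENARIOS[scenario].conditions):
                cells[(scenario, variant, condition)] = run_experiment(
                    scenario, variant, condition, n_trials, seed, **trial_kwargs
                )
    return cells


def selections_frame(cells: Mapping[tuple, ExperimentCell]) -> pd.DataFrame:
    rows = []
    for (scenario, variant, condition), cell in cells.items():
        for i, sel in enumerate(cell.selections):
            rows.append(
                {
                    "scenario": scenario,
                    "variant": variant,
                    "condition": condition,
                    "trial": i,
                    "selected_policy": int(sel) + 1,
                }
            )
    return pd.DataFrame(rows)


def counts_table(cells: Mapping[tuple, ExperimentCell]) -> pd.DataFrame:
    """Counts with one row per policy 1..7, one column per variant x condition."""
    data = {}
    for (scenario, variant, condition), cell in sorted(cells.items()):
        data[f"{scenario}/{variant}/{condition}"] = cell.counts
    return pd.DataFrame(data, index=[f"P{i + 1}" for i in range(N_POLICIES)])


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------


@dataclass
class ExperimentSummary:
    counts: pd.DataFrame
    cell_metrics: dict
    fold_changes: dict
    intervals: dict
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {col: self.counts[col].tolist() for col in self.counts},
            "cell_metrics": self.cell_metrics,
            "fold_changes": self.fold_changes,
            "intervals": self.intervals,
            "flags": self.flags,
        }


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def _boot_ratio(sel_num, sel_den, stat, rng, n_boot):
    vals = np.empty(n_boot)
    n1, n2 = len(sel_num), len(sel_den)
    for b in range(n_boot):
        s1 = sel_num[rng.integers(0, n1, n1)]
        s2 = sel_den[rng.integers(0, n2, n2)]
        vals[b] = _ratio(stat(s1), stat(s2))
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return [math.nan, math.nan]
    return [float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))]


def summarize(
    cells: Mapping[tuple, ExperimentCell],
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> ExperimentSummary:
    """Phenotype metrics over a grid of experiment cells.

    Computes per-cell selection metrics, the hard-freeze fold change
    (variant IV vs II) per scenario-2 condition, and the relaxed
    resumption contrast (variant I vs III) per condition, each with a
    bootstrap percentile interval over trials.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xB007)))
    cell_metrics = {}
    for key, cell in cells.items():
        cell_metrics["/".join(key)] = cell.metric_counts()

    fold_changes: dict = {}
    intervals: dict = {}
    flags: list[str] = []

    def hard_freeze(sel):
        return float((sel == HARD_FREEZE_POLICY).sum())

    def relaxed(sel):
        return float(np.isin(sel, RELAXED_RESUMPTION_POLICIES).sum())

    by_key = dict(cells)
    scen_conds = sorted({(k[0], k[2]) for k in cells})
    for scenario, condition in scen_conds:
        iv = by_key.get((scenario, "IV", condition))
        ii = by_key.get((scenario, "II", condition))
        if iv is not None and ii is not None:
            name = f"hard_freeze_IV_vs_II/{scenario}/{condition}"
            num, den = hard_freeze(iv.selections), hard_freeze(ii.selections)
            fold_changes[name] = _ratio(num, den)
            if den == 0:
                flags.append(f"{name}: zero count in the denominator cell")
            intervals[name] = _boot_ratio(
                iv.selections, ii.selections, hard_freeze, rng, n_boot
            )
        ci = by_key.get((scenario, "I", condition))
        ciii = by_key.get((scenario, "III", condition))
        if ci is not None and ciii is not None:
            name = f"relaxed_resumption_I_vs_III/{scenario}/{condition}"
            num, den = relaxed(ci.selections), relaxed(ciii.selections)
            fold_changes[name] = _ratio(num, den)
            if den == 0:
                flags.append(f"{name}: zero count in the denominator cell")
            intervals[name] = _boot_ratio(
                ci.selections, ciii.selections, relaxed, rng, n_boot
            )

    return ExperimentSummary(
        counts=counts_table(cells),
        cell_metrics=cell_metrics,
        fold_changes=fold_changes,
        intervals=intervals,
        flags=flags,
    )
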