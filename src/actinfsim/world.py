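"""The generative process: the true environment behind the agent's senses.

The process shares the model's parametric kernels (likelihood and
transition families built from the same :class:`ModelConfig`), so the
agent is veridical apart from its priors.  Scenarios clamp the epoch-1
exteroceptive outcomes to the narrative openings (empty horizon + soft
sound, or dot on the horizon); later outcomes are sampled, unless a
scripted trajectory override is supplied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_spec import (
    AUD_SOFT,
    ENV_CAT_DISTAL,
    ENV_DOG_DISTAL,
    ENV_LEVELS,
    ENV_NONE,
    HEART_HIGH,
    HEART_LOW,
    MOVING,
    STILL,
    VIS_DOT,
    VIS_EMPTY,
    FIGHT_FLIGHT,
    ORIENT,
    ROAM,
    ModelConfig,
    build_jerry_model,
)

__all__ = ["WorldState", "Scenario", "SCENARIOS", "World", "proprio_outcome"]


@dataclass(frozen=True)
class WorldState:
    env: int
    motion: int
    heart: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.env, self.motion, self.heart)


@dataclass(frozen=True)
class Scenario:
    """A narrative opening: initial-state conditions and clamped outcomes."""

    id: str
    conditions: dict  # condition label -> initial creatures level
    clamped_vision: int
    clamped_audition: int


SCENARIOS: dict[str, Scenario] = {
    "scenario1": Scenario(
        id="scenario1",
        conditions={"a": ENV_NONE, "b": ENV_CAT_DISTAL, "c": ENV_DOG_DISTAL},
        clamped_vision=VIS_EMPTY,
        clamped_audition=AUD_SOFT,
    ),
    "scenario2": Scenario(
        id="scenario2",
        conditions={"d": ENV_CAT_DISTAL, "e": ENV_DOG_DISTAL},
        clamped_vision=VIS_DOT,
        clamped_audition=AUD_SOFT,
    ),
}


def proprio_outcome(motion: int, heart: int) -> int:
    """Deterministic joint proprio-/baroreceptive readout."""
    return 2 * heart + motion


class World:
    """The true environment; issues outcomes and reacts to actions.

    scripted_env: optional sequence of creatures-level indices, one per
    epoch, overriding the stochastic kernel (the single-trial narratives
    of the source scenarios are scripted in this sense).
    scripted_outcomes: optional (epoch -> (audition, vision, proprio))
    overrides for sampled outcomes.
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        *,
        scripted_env: Sequence[int] | None = None,
        scripted_outcomes: dict[int, tuple[int, int, int]] | None = None,
    ) -> None:
        self.config = config or ModelConfig()
        # process kernels == model kernels built from the same config
        ref = build_jerry_model(self.config)
        self.A = ref.A
        self.B = ref.B
        self.scripted_env = None if scripted_env is None else [int(e) for e in scripted_env]
        self.scripted_outcomes = dict(scripted_outcomes or {})

    # ------------------------------------------------------------------

    def init_trial(self, scenario: Scenario | str, condition: str):
        """Start a trial: returns (WorldState, epoch-1 outcome indices)."""
        if isinstance(scenario, str):
            scenario = SCENARIOS[scenario]
        if condition not in scenario.conditions:
            raise ValueError(
                f"condition {condition!r} not in scenario {scenario.id!r} "
                f"(choose from {sorted(scenario.conditions)})"
            )
        env = scenario.conditions[condition]
        if self.scripted_env is not None:
            env = self.scripted_env[0]
        state = WorldState(env=env, motion=MOVING, heart=HEART_LOW)
        outcomes = (
            scenario.clamped_audition,
            scenario.clamped_vision,
            proprio_outcome(state.motion, state.heart),
        )
        if 0 in self.scripted_outcomes:
            outcomes = tuple(self.scripted_outcomes[0])
        return state, outcomes

    def step_world(
        self, state: WorldState, action: int, rng: np.random.Generator, epoch: int | None = None
    ) -> WorldState:
        """Advance the true state under an action.

        ``epoch`` is the index (0-based) of the epoch being entered; it is
        only needed when a scripted trajectory is active.
        """
        if self.scripted_env is not None:
            if epoch is None:
                raise ValueError("scripted world needs the target epoch index")
            env = self.scripted_env[epoch]
        else:
            probs = self.B[0][action][:, state.env]
            env = int(rng.choice(len(ENV_LEVELS), p=probs))
        motion = MOVING if action in (ROAM, FIGHT_FLIGHT) else STILL
        heart = HEART_HIGH if action in (ORIENT, FIGHT_FLIGHT) else HEART_LOW
        return WorldState(env=env, motion=motion, heart=heart)

    def emit_outcomes(
        self, state: WorldState, rng: np.random.Generator, epoch: int | None = None
    ) -> tuple[int, int, int]:
        """Sample one outcome index per modality from the true likelihood."""
        if epoch is not None and epoch in self.scripted_outcomes:
            return tuple(self.scripted_outcomes[epoch])
        out = []
        for arr in self.A:
            probs = arr[:, state.env, state.motion, state.heart]
            out.append(int(rng.choice(arr.shape[0], p=probs)))
        return tuple(out)
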