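"""Typed containers and builders for the defensive-foraging generative model.

The agent ("Jerry") lives in a world with three hidden-state factors
(nearby creatures, self-motion, heart rate) and three outcome modalities
(audition, vision, joint proprio-/baroreception).  This module defines the
canonical level orderings, the dataclasses that hold the categorical
arrays (A likelihoods, B transitions, C preferences, D initial priors,
policy set U/E), validators, and the builders for the default intact /
lesioned, safe / unsafe parameterisations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FactorSpec",
    "ModalitySpec",
    "PolicySet",
    "GenerativeModel",
    "ModelConfig",
    "ValidationReport",
    "Violation",
    "ModelValidationError",
    "build_jerry_model",
    "build_policy_set",
    "validate_model",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

# ---------------------------------------------------------------------------
# Canonical orderings
# ---------------------------------------------------------------------------

ENV_LEVELS = ("none", "cat-distal", "dog-distal", "cat-proximal", "dog-proximal")
MOTION_LEVELS = ("moving", "still")
HEART_LEVELS = ("moderate-low", "high")

AUDITION_LEVELS = ("silence", "soft-sound", "loud-sound")
VISION_LEVELS = ("empty-horizon", "dot-on-horizon", "dog-shape", "cat-shape", "blur")
PROPRIO_LEVELS = (
    "no-pressure-moving",
    "no-pressure-still",
    "pressure-moving",
    "pressure-still",
)

ACTION_LABELS = ("roam-scan", "orient", "fight-or-flight", "freeze")
ROAM, ORIENT, FIGHT_FLIGHT, FREEZE = range(4)

ENV_NONE, ENV_CAT_DISTAL, ENV_DOG_DISTAL, ENV_CAT_PROXIMAL, ENV_DOG_PROXIMAL = range(5)
MOVING, STILL = range(2)
HEART_LOW, HEART_HIGH = range(2)

AUD_SILENCE, AUD_SOFT, AUD_LOUD = range(3)
VIS_EMPTY, VIS_DOT, VIS_DOG, VIS_CAT, VIS_BLUR = range(5)

FACTOR_NAMES = ("creatures", "motion", "heart")
MODALITY_NAMES = ("audition", "vision", "proprio-baro")

N_POLICIES = 7
N_STEPS = 5
HORIZON = 6

PROB_TOL = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorSpec:
    """A hidden-state factor: a name and its ordered level labels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r} has duplicate level labels")

    @property
    def n(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ModalitySpec:
    """An outcome modality: a name and its ordered outcome labels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"modality {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"modality {self.name!r} has duplicate level labels")

    @property
    def n(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class PolicySet:
    """The policy array U (action index per step x policy) and prior bias E."""

    actions: tuple[str, ...]
    U: np.ndarray  # (n_steps, n_policies) of action indices
    E: np.ndarray  # (n_policies,) prior bias, sums to 1
    labels: tuple[str, ...] = ()

    @property
    def n_policies(self) -> int:
        return self.U.shape[1]

    @property
    def n_steps(self) -> int:
        return self.U.shape[0]


@dataclass(frozen=True)
class ModelConfig:
    """Free parameters for the default model family.

    eps_sound: probability of a spurious (soft or loud) distal sound when
        no creatures are present.
    p_attract: per-step probability that a distal cat approaches while the
        agent is moving or has a high heart rate (roam / orient actions);
        also gates creature entry into the distal scene.
    p_evade: per-step probability that fight-or-flight or freeze increases
        the distance to a creature.
    p_wander: per-step probability that a creature drifts within / out of
        the distal scene of its own accord.
    """

    lesioned: bool = False
    context: str = "safe"  # {"safe", "unsafe"}
    eps_sound: float = 0.1
    p_attract: float = 0.28
    p_evade: float = 0.9
    p_wander: float = 0.18

    def __post_init__(self) -> None:
        if self.context not in ("safe", "unsafe"):
            raise ValueError(f"context must be 'safe' or 'unsafe', got {self.context!r}")
        for name in ("eps_sound", "p_attract", "p_evade", "p_wander"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class GenerativeModel:
    """The complete categorical generative model.

    A[m]: (n_outcomes_m, n_env, n_motion, n_heart) likelihood tensors.
    B[f]: (n_actions, n_f, n_f) transition matrices, B[f][a][to, from].
    C[m]: (n_outcomes_m,) log-prior preference offsets over outcomes.
    D[f]: (n_f,) prior over initial states.
    """

    factors: tuple[FactorSpec, ...]
    modalities: tuple[ModalitySpec, ...]
    A: tuple[np.ndarray, ...]
    B: tuple[np.ndarray, ...]
    C: tuple[np.ndarray, ...]
    D: tuple[np.ndarray, ...]
    policies: PolicySet
    horizon: int = HORIZON
    config: ModelConfig | None = None

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def state_shape(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    def factor_index(self, name: str) -> int:
        return [f.name for f in self.factors].index(name)

    def modality_index(self, name: str) -> int:
        return [m.name for m in self.modalities].index(name)


class ModelValidationError(ValueError):
    """Raised when a builder receives an invalid configuration."""


@dataclass(frozen=True)
class Violation:
    kind: str  # e.g. "normalization", "negative", "dimension", "policy-prefix"
    location: str  # human-readable array coordinates
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.location}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, location: str, detail: str = "") -> None:
        self.violations.append(Violation(kind, location, detail))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _default_factors() -> tuple[FactorSpec, ...]:
    return (
        FactorSpec("creatures", ENV_LEVELS),
        FactorSpec("motion", MOTION_LEVELS),
        FactorSpec("heart", HEART_LEVELS),
    )


def _default_modalities() -> tuple[ModalitySpec, ...]:
    return (
        ModalitySpec("audition", AUDITION_LEVELS),
        ModalitySpec("vision", VISION_LEVELS),
        ModalitySpec("proprio-baro", PROPRIO_LEVELS),
    )


def build_policy_set() -> PolicySet:
    """The seven allowable policies over five action steps.

    All policies begin with roam-scan then orient.  Policies 1-3 continue
    with fight-or-flight (unrelenting / back to orienting / back to
    roaming); policies 4-6 are the freeze counterparts; policy 7
    alternates roaming and orienting and contains neither defence.
    """
    U = np.array(
        [
            # P1   P2   P3   P4   P5   P6   P7
            [ROAM, ROAM, ROAM, ROAM, ROAM, ROAM, ROAM],
            [ORIENT, ORIENT, ORIENT, ORIENT, ORIENT, ORIENT, ORIENT],
            [FIGHT_FLIGHT, FIGHT_FLIGHT, FIGHT_FLIGHT, FREEZE, FREEZE, FREEZE, ROAM],
            [FIGHT_FLIGHT, ORIENT, ROAM, FREEZE, ORIENT, ROAM, ORIENT],
            [FIGHT_FLIGHT, ORIENT, ROAM, FREEZE, ORIENT, ROAM, ROAM],
        ],
        dtype=np.int64,
    )
    E = np.full(N_POLICIES, 1.0 / N_POLICIES)
    labels = tuple(f"P{i + 1}" for i in range(N_POLICIES))
    return PolicySet(actions=ACTION_LABELS, U=U, E=E, labels=labels)


def _build_A(cfg: ModelConfig) -> tuple[np.ndarray, ...]:
    n_env, n_mot, n_hrt = 5, 2, 2
    eps = cfg.eps_sound

    # Audition depends only on the creatures factor.
    A_aud = np.zeros((3, n_env, n_mot, n_hrt))
    col = np.empty(3)
    for e in range(n_env):
        if e == ENV_NONE:
            col[:] = (1.0 - eps, eps / 2.0, eps / 2.0)
        elif e in (ENV_CAT_DISTAL, ENV_DOG_DISTAL):
            col[:] = (0.2, 0.8, 0.0)
        else:  # proximal
            col[:] = (0.0, 0.2, 0.8)
        A_aud[:, e, :, :] = col[:, None, None]

    # Vision depends on all three factors.
    A_vis = np.zeros((5, n_env, n_mot, n_hrt))
    for e in range(n_env):
        for m in range(n_mot):
            for h in range(n_hrt):
                col5 = np.zeros(5)
                if m == MOVING and h == HEART_HIGH:
                    col5[VIS_BLUR] = 1.0  # motion blur regardless of scene
                elif m == MOVING and e in (ENV_CAT_DISTAL, ENV_DOG_DISTAL):
                    col5[VIS_DOT] = 0.5
                    col5[VIS_EMPTY] = 0.5
                else:  # veridical view
                    if e == ENV_NONE:
                        col5[VIS_EMPTY] = 1.0
                    elif e in (ENV_CAT_DISTAL, ENV_DOG_DISTAL):
                        col5[VIS_DOT] = 1.0
                    elif e == ENV_CAT_PROXIMAL:
                        col5[VIS_CAT] = 1.0
                    else:
                        col5[VIS_DOG] = 1.0
                A_vis[:, e, m, h] = col5

    # Joint proprio-/baroreception reads motion x heart deterministically.
    A_pb = np.zeros((4, n_env, n_mot, n_hrt))
    for m in range(n_mot):
        for h in range(n_hrt):
            idx = 2 * h + m  # (no-press, press) x (moving, still)
            A_pb[idx, :, m, h] = 1.0

    return (A_aud, A_vis, A_pb)


def _build_B(cfg: ModelConfig) -> tuple[np.ndarray, ...]:
    pa, pe, pw = cfg.p_attract, cfg.p_evade, cfg.p_wander

    B_env = np.zeros((4, 5, 5))
    for a in (ROAM, ORIENT):
        T = np.zeros((5, 5))
        # entry into the distal scene is gated by attraction
        T[ENV_CAT_DISTAL, ENV_NONE] = pw * pa / 2.0
        T[ENV_DOG_DISTAL, ENV_NONE] = pw * pa / 2.0
        T[ENV_NONE, ENV_NONE] = 1.0 - pw * pa
        # a distal cat is drawn in by movement / heart rate
        T[ENV_CAT_PROXIMAL, ENV_CAT_DISTAL] = pa
        T[ENV_NONE, ENV_CAT_DISTAL] = (1.0 - pa) * pw
        T[ENV_CAT_DISTAL, ENV_CAT_DISTAL] = (1.0 - pa) * (1.0 - pw)
        # the dog is indifferent to the agent and merely wanders
        T[ENV_DOG_PROXIMAL, ENV_DOG_DISTAL] = pw / 2.0
        T[ENV_NONE, ENV_DOG_DISTAL] = pw / 2.0
        T[ENV_DOG_DISTAL, ENV_DOG_DISTAL] = 1.0 - pw
        T[ENV_CAT_PROXIMAL, ENV_CAT_PROXIMAL] = 1.0
        T[ENV_DOG_DISTAL, ENV_DOG_PROXIMAL] = pw / 2.0
        T[ENV_DOG_PROXIMAL, ENV_DOG_PROXIMAL] = 1.0 - pw / 2.0
        B_env[a] = T
    # Fight-or-flight actively opens distance from either creature.
    T = np.zeros((5, 5))
    T[ENV_NONE, ENV_NONE] = 1.0
    T[ENV_NONE, ENV_CAT_DISTAL] = pe
    T[ENV_CAT_DISTAL, ENV_CAT_DISTAL] = 1.0 - pe
    T[ENV_CAT_DISTAL, ENV_CAT_PROXIMAL] = pe
    T[ENV_CAT_PROXIMAL, ENV_CAT_PROXIMAL] = 1.0 - pe
    T[ENV_NONE, ENV_DOG_DISTAL] = pe
    T[ENV_DOG_DISTAL, ENV_DOG_DISTAL] = 1.0 - pe
    T[ENV_DOG_DISTAL, ENV_DOG_PROXIMAL] = pe
    T[ENV_DOG_PROXIMAL, ENV_DOG_PROXIMAL] = 1.0 - pe
    B_env[FIGHT_FLIGHT] = T

    # Freezing is concealment: a distal cat loses interest and wanders
    # off, but a proximal cat is not displaced, and the indifferent dog
    # just keeps wandering.
    T = np.zeros((5, 5))
    T[ENV_NONE, ENV_NONE] = 1.0
    T[ENV_NONE, ENV_CAT_DISTAL] = pw
    T[ENV_CAT_DISTAL, ENV_CAT_DISTAL] = 1.0 - pw
    T[ENV_CAT_PROXIMAL, ENV_CAT_PROXIMAL] = 1.0
    T[ENV_DOG_PROXIMAL, ENV_DOG_DISTAL] = pw / 2.0
    T[ENV_NONE, ENV_DOG_DISTAL] = pw / 2.0
    T[ENV_DOG_DISTAL, ENV_DOG_DISTAL] = 1.0 - pw
    T[ENV_DOG_DISTAL, ENV_DOG_PROXIMAL] = pw / 2.0
    T[ENV_DOG_PROXIMAL, ENV_DOG_PROXIMAL] = 1.0 - pw / 2.0
    B_env[FREEZE] = T

    # Motion and heart follow the selected action deterministically.
    B_mot = np.zeros((4, 2, 2))
    for a in range(4):
        nxt = MOVING if a in (ROAM, FIGHT_FLIGHT) else STILL
        B_mot[a, nxt, :] = 1.0

    B_hrt = np.zeros((4, 2, 2))
    for a in range(4):
        nxt = HEART_HIGH if a in (ORIENT, FIGHT_FLIGHT) else HEART_LOW
        B_hrt[a, nxt, :] = 1.0

    return (B_env, B_mot, B_hrt)


#: Intact / lesioned cat-shape preference (log-probability offsets).
C_CAT_INTACT = -6.25
C_CAT_LESIONED = -10.0


def _build_C(cfg: ModelConfig) -> tuple[np.ndarray, ...]:
    c_aud = np.array([1.0, -1.0, -2.0])
    cat = C_CAT_LESIONED if cfg.lesioned else C_CAT_INTACT
    # order: horizon, dot, dog, cat, blur
    c_vis = np.array([2.0, -1.0, 1.0, cat, -0.5])
    # order: no-pressure moving / still, pressure moving / still; the
    # orienting outcome (pressure + still) is neutral.
    c_pb = np.array([1.0, -1.0, -10.0, 0.0])
    return (c_aud, c_vis, c_pb)


def _build_D(cfg: ModelConfig) -> tuple[np.ndarray, ...]:
    if cfg.context == "unsafe":
        d_env = np.zeros(5)
        d_env[ENV_CAT_DISTAL] = 1.0
    else:
        d_env = np.full(5, 0.2)
    d_mot = np.array([1.0, 0.0])  # trials begin while roaming
    d_hrt = np.array([1.0, 0.0])
    return (d_env, d_mot, d_hrt)


def build_jerry_model(config: ModelConfig | None = None) -> GenerativeModel:
    """Build the default agent model for a configuration.

    Raises ModelValidationError (naming the offending field) if the
    configuration is invalid, and asserts that the built model passes
    :func:`validate_model`.
    """
    if config is None:
        config = ModelConfig()
    if not isinstance(config, ModelConfig):
        try:
            config = ModelConfig(**dict(config))
        except TypeError as exc:
            raise ModelValidationError(str(exc)) from exc
    model = GenerativeModel(
        factors=_default_factors(),
        modalities=_default_modalities(),
        A=_build_A(config),
        B=_build_B(config),
        C=_build_C(config),
        D=_build_D(config),
        policies=build_policy_set(),
        horizon=HORIZON,
        config=config,
    )
    report = validate_model(model)
    if not report.ok:  # pragma: no cover - builder guarantee
        raise ModelValidationError("; ".join(str(v) for v in report.violations))
    return model


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_dist(vec: np.ndarray, location: str, report: ValidationReport) -> None:
    if np.any(vec < 0):
        idx = int(np.argmin(vec))
        report.add("negative", f"{location}[{idx}]", f"value {vec[idx]:g}")
    s = float(vec.sum())
    if abs(s - 1.0) > PROB_TOL:
        report.add("normalization", location, f"sums to {s!r}")


def validate_model(model: GenerativeModel) -> ValidationReport:
    """Report every violated structural invariant of a generative model."""
    report = ValidationReport()
    shape = model.state_shape

    if len(model.A) != len(model.modalities):
        report.add("dimension", "A", "one array per modality required")
    for m, (spec, arr) in enumerate(zip(model.modalities, model.A)):
        want = (spec.n, *shape)
        if arr.shape != want:
            report.add("dimension", f"A[{spec.name}]", f"shape {arr.shape} != {want}")
            continue
        flat = arr.reshape(spec.n, -1)
        for j in range(flat.shape[1]):
            coords = tuple(int(c) for c in np.unravel_index(j, shape))
            _check_dist(flat[:, j], f"A[{spec.name}]{coords}", report)

    n_actions = len(model.policies.actions)
    if len(model.B) != len(model.factors):
        report.add("dimension", "B", "one array per factor required")
    for f, (spec, arr) in enumerate(zip(model.factors, model.B)):
        want = (n_actions, spec.n, spec.n)
        if arr.shape != want:
            report.add("dimension", f"B[{spec.name}]", f"shape {arr.shape} != {want}")
            continue
        for a in range(n_actions):
            for s_from in range(spec.n):
                _check_dist(
                    arr[a, :, s_from], f"B[{spec.name}][{a},:,{s_from}]", report
                )

    for spec, vec in zip(model.modalities, model.C):
        if vec.shape != (spec.n,):
            report.add("dimension", f"C[{spec.name}]", f"shape {vec.shape} != ({spec.n},)")
        elif not np.all(np.isfinite(vec)):
            report.add("non-finite", f"C[{spec.name}]", "preferences must be finite")

    for spec, vec in zip(model.factors, model.D):
        if vec.shape != (spec.n,):
            report.add("dimension", f"D[{spec.name}]", f"shape {vec.shape} != ({spec.n},)")
        else:
            _check_dist(vec, f"D[{spec.name}]", report)

    U = model.policies.U
    if U.shape != (N_STEPS, U.shape[1]):
        report.add("dimension", "U", f"expected {N_STEPS} action steps")
    for p in range(U.shape[1]):
        if not (U[0, p] == ROAM and U[1, p] == ORIENT):
            report.add(
                "policy-prefix",
                f"U[:, {p}]",
                "every policy must begin roam-scan then orient",
            )
    _check_dist(model.policies.E, "E", report)

    if model.horizon != N_STEPS + 1:
        report.add("dimension", "horizon", f"{model.horizon} != action steps + 1")

    # cat <-> dog identity changes are impossible under every action
    if model.factors and model.factors[0].levels == ENV_LEVELS and not any(
        v.kind == "dimension" for v in report.violations
    ):
        cat = (ENV_CAT_DISTAL, ENV_CAT_PROXIMAL)
        dog = (ENV_DOG_DISTAL, ENV_DOG_PROXIMAL)
        B_env = model.B[0]
        for a in range(n_actions):
            for i in cat:
                for j in dog:
                    if B_env[a, j, i] != 0.0 or B_env[a, i, j] != 0.0:
                        report.add(
                            "forbidden-transition",
                            f"B[creatures][{a}] between {ENV_LEVELS[i]} and {ENV_LEVELS[j]}",
                        )
    return report


# ---------------------------------------------------------------------------
# Serialization (round-trippable YAML/JSON documents)
# ---------------------------------------------------------------------------


def model_to_dict(model: GenerativeModel) -> dict:
    doc: dict = {
        "factors": [{"name": f.name, "levels": list(f.levels)} for f in model.factors],
        "modalities": [
            {"name": m.name, "levels": list(m.levels)} for m in model.modalities
        ],
        "A": {m.name: a.tolist() for m, a in zip(model.modalities, model.A)},
        "B": {f.name: b.tolist() for f, b in zip(model.factors, model.B)},
        "C": {m.name: c.tolist() for m, c in zip(model.modalities, model.C)},
        "D": {f.name: d.tolist() for f, d in zip(model.factors, model.D)},
        "E": model.policies.E.tolist(),
        "U": model.policies.U.tolist(),
        "actions": list(model.policies.actions),
        "horizon": model.horizon,
    }
    if model.config is not None:
        doc["config"] = {
            "lesioned": model.config.lesioned,
            "context": model.config.context,
            "eps_sound": model.config.eps_sound,
            "p_attract": model.config.p_attract,
            "p_evade": model.config.p_evade,
            "p_wander": model.config.p_wander,
        }
    return doc


def model_from_dict(doc: Mapping) -> GenerativeModel:
    factors = tuple(FactorSpec(f["name"], tuple(f["levels"])) for f in doc["factors"])
    modalities = tuple(
        ModalitySpec(m["name"], tuple(m["levels"])) for m in doc["modalities"]
    )
    A = tuple(np.asarray(doc["A"][m.name], dtype=float) for m in modalities)
    B = tuple(np.asarray(doc["B"][f.name], dtype=float) for f in factors)
    C = tuple(np.asarray(doc["C"][m.name], dtype=float) for m in modalities)
    D = tuple(np.asarray(doc["D"][f.name], dtype=float) for f in factors)
    U = np.asarray(doc["U"], dtype=np.int64)
    E = np.asarray(doc["E"], dtype=float)
    policies = PolicySet(actions=tuple(doc["actions"]), U=U, E=E)
    config = None
    if "config" in doc:
        config = ModelConfig(**doc["config"])
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        horizon=int(doc["horizon"]),
        config=config,
    )


def save_model(model: GenerativeModel, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> GenerativeModel:
    import yaml

    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def variant_config(variant: str, **free_params) -> ModelConfig:
    """Map an experiment variant id (I-IV) to a ModelConfig."""
    table = {
        "I": (False, "safe"),
        "II": (False, "unsafe"),
        "III": (True, "safe"),
        "IV": (True, "unsafe"),
    }
    if variant not in table:
        raise ModelValidationError(f"unknown variant {variant!r} (expected I-IV)")
    lesioned, context = table[variant]
    return ModelConfig(lesioned=lesioned, context=context, **free_params)
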