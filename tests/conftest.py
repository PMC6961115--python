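import numpy as np
import pytest

from actinfsim.model_spec import (
    FactorSpec,
    GenerativeModel,
    ModalitySpec,
    ModelConfig,
    build_jerry_model,
    build_policy_set,
)


@pytest.fixture(scope="session")
def intact_model():
    return build_jerry_model(ModelConfig())


@pytest.fixture(scope="session")
def lesioned_model():
    return build_jerry_model(ModelConfig(lesioned=True))


@pytest.fixture(scope="session")
def unsafe_model():
    return build_jerry_model(ModelConfig(context="unsafe"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_small_model(
    rng: np.random.Generator,
    *,
    n_factors: int = 2,
    max_levels: int = 3,
    horizon: int = 6,
    coupled: bool = False,
) -> GenerativeModel:
    """A random small categorical model for oracle comparisons.

    By default each modality reads a single factor, so the posterior is
    exactly solvable by local message passing; ``coupled=True`` adds a
    modality that reads every factor jointly.
    """
    sizes = [int(rng.integers(2, max_levels + 1)) for _ in range(n_factors)]
    factors = tuple(
        FactorSpec(f"f{i}", tuple(f"l{j}" for j in range(s)))
        for i, s in enumerate(sizes)
    )
    mods = []
    A = []
    for i, s in enumerate(sizes):
        n_out = int(rng.integers(2, max_levels + 1))
        mods.append(ModalitySpec(f"m{i}", tuple(f"o{j}" for j in range(n_out))))
        cols = rng.dirichlet(np.ones(n_out), size=s).T  # (n_out, s)
        shape = [n_out] + [1] * n_factors
        shape[1 + i] = s
        A.append(np.broadcast_to(cols.reshape(shape), (n_out, *sizes)).copy())
    if coupled:
        n_out = int(rng.integers(2, max_levels + 1))
        mods.append(
            ModalitySpec("joint", tuple(f"o{j}" for j in range(n_out)))
        )
        n_states = int(np.prod(sizes))
        cols = rng.dirichlet(np.ones(n_out), size=n_states).T
        A.append(cols.reshape(n_out, *sizes))
    B = tuple(
        np.stack([rng.dirichlet(np.ones(s), size=s).T for _ in range(4)])
        for s in sizes
    )
    D = tuple(rng.dirichlet(np.ones(s)) for s in sizes)
    C = tuple(np.zeros(m.n) for m in mods)
    return GenerativeModel(
        factors=factors,
        modalities=tuple(mods),
        A=tuple(A),
        B=B,
        C=C,
        D=D,
        policies=build_policy_set(),
        horizon=horizon,
    )
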