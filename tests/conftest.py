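import numpy as np
import pytest

from infagree import ContingencyTable, JointDistribution, ProbabilityVector, TransitionMatrix


def random_joint(rng: np.random.Generator, q: int) -> JointDistribution:
    """A strictly positive random joint distribution (Dirichlet cells)."""
    probs = rng.dirichlet(np.ones(q * q)).reshape(q, q)
    # Dirichlet can produce denormal-tiny cells; keep them strictly positive
    probs = probs + 1e-9
    return JointDistribution(probs / probs.sum())


def random_table(rng: np.random.Generator, q: int, n: int) -> ContingencyTable:
    """A random contingency table with every marginal occupied."""
    while True:
        cells = rng.multinomial(n, rng.dirichlet(np.ones(q * q)))
        table = cells.reshape(q, q)
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            return ContingencyTable(table)


def random_channel(rng: np.random.Generator, q: int) -> tuple[ProbabilityVector, TransitionMatrix]:
    """A random nondegenerate (input distribution, transition matrix) pair."""
    px = rng.dirichlet(np.ones(q)) + 1e-6
    gamma = rng.dirichlet(np.ones(q), size=q).T + 1e-6  # columns ~ Dirichlet
    return (
        ProbabilityVector(px / px.sum()),
        TransitionMatrix(gamma / gamma.sum(axis=0)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261002)


@pytest.fixture
def scenario5() -> ContingencyTable:
    return ContingencyTable([[40, 5], [3, 2]])


@pytest.fixture
def birads_5x5() -> ContingencyTable:
    return ContingencyTable(
        [
            [51, 4, 0, 1, 1],
            [3, 78, 1, 0, 0],
            [0, 0, 13, 4, 0],
            [0, 1, 1, 16, 7],
            [0, 0, 0, 0, 5],
        ]
    )
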