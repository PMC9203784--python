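import numpy as np
import pytest

from crossimpact import (
    CrossImpactMatrix,
    GoalRegistry,
    InteractionScore,
    build_matrix,
)
from crossimpact.synthetic import (
    cambodia_child_health_matrix,
    cambodia_goal_registry,
    cambodia_indicator_series,
)


@pytest.fixture
def abc_registry():
    return GoalRegistry(["A", "B", "C"])


@pytest.fixture
def toy_matrix(abc_registry):
    """W = {A->B: 2, A->C: 1, B->C: 3, all other links 0}."""
    scores = [
        InteractionScore("A", "B", 2),
        InteractionScore("A", "C", 1),
        InteractionScore("B", "C", 3),
        InteractionScore("B", "A", 0),
        InteractionScore("C", "A", 0),
        InteractionScore("C", "B", 0),
    ]
    return build_matrix(abc_registry, scores)


@pytest.fixture(scope="session")
def cambodia_registry():
    return cambodia_goal_registry()


@pytest.fixture(scope="session")
def child_health_matrix():
    """17-goal matrix embedding the child-health row/column, zeros elsewhere."""
    return cambodia_child_health_matrix()


@pytest.fixture(scope="session")
def cambodia_series():
    return cambodia_indicator_series()


def random_matrix(rng: np.random.Generator, n: int) -> CrossImpactMatrix:
    """Unconstrained random complete matrix on n generic goals."""
    w = rng.integers(-3, 4, size=(n, n))
    np.fill_diagonal(w, 0)
    return CrossImpactMatrix(GoalRegistry([f"G{i}" for i in range(n)]), w)
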