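"""The cross-impact matrix: a complete, integer-weighted directed network.

Cell (i, j) holds w_ij, the scored influence of progress on goal i upon
progress on goal j, on the seven-point scale. Self-influence is never scored:
diagonal cells are structurally absent, not zero, and every aggregate in the
package skips i = j. A matrix on n goals therefore stores exactly n(n-1)
directed links — the network G = (N, L) with goals as nodes and scored pairs
as links.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateInteractionError,
    IncompleteMatrixError,
    ScoreRangeError,
    SelfInteractionError,
)
from .goals import GoalRegistry
from .scale import validate_score


@dataclass(frozen=True)
class InteractionScore:
    """One directed scored pair: source influences target with `score`.

    ``motivation`` carries the scorers' 1-2 sentence rationale; ``provenance``
    tags which group (or "consensus") the score came from.
    """

    source: str
    target: str
    score: int
    motivation: str | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise SelfInteractionError(
                f"self-interaction {self.source!r}->{self.target!r} not allowed"
            )
        object.__setattr__(self, "score", validate_score(self.score))


class CrossImpactMatrix:
    """Complete matrix of integer scores w_ij over an ordered goal registry.

    Construct via :func:`build_matrix` (from a score list), :meth:`from_frame`
    (from a goals x goals DataFrame with an NA diagonal), or the IO readers.
    Instances are immutable.
    """

    def __init__(self, registry: GoalRegistry, weights: np.ndarray):
        n = len(registry)
        weights = np.asarray(weights)
        if weights.shape != (n, n):
            raise ScoreRangeError(
                f"weight table shape {weights.shape} does not match {n} goals"
            )
        if not np.issubdtype(weights.dtype, np.integer):
            if not np.all(np.equal(np.mod(weights, 1), 0)):
                raise ScoreRangeError("fractional weights are not allowed")
            weights = weights.astype(np.int64)
        off = ~np.eye(n, dtype=bool)
        if weights[off].min(initial=0) < -3 or weights[off].max(initial=0) > 3:
            raise ScoreRangeError("weights outside the seven-point scale -3..+3")
        w = weights.astype(np.int64).copy()
        np.fill_diagonal(w, 0)  # diagonal is structurally absent; 0 internally
        w.setflags(write=False)
        self._registry = registry
        self._w = w

    # -- basic introspection -------------------------------------------------

    @property
    def registry(self) -> GoalRegistry:
        return self._registry

    @property
    def goals(self) -> tuple[str, ...]:
        return self._registry.ids

    @property
    def n_goals(self) -> int:
        return len(self._registry)

    @property
    def n_links(self) -> int:
        """Number of stored directed links: always n(n-1)."""
        n = self.n_goals
        return n * (n - 1)

    def values(self) -> np.ndarray:
        """Read-only (n, n) integer array with zeros on the (absent) diagonal."""
        return self._w

    def weight(self, source: str, target: str) -> int:
        """w_{source,target}; raises on the diagonal."""
        i = self._registry.index(source)
        j = self._registry.index(target)
        if i == j:
            raise SelfInteractionError(
                f"self-interaction {source!r} has no weight (diagonal undefined)"
            )
        return int(self._w[i, j])

    def __contains__(self, goal: object) -> bool:
        return goal in self._registry

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CrossImpactMatrix)
            and self.goals == other.goals
            and np.array_equal(self._w, other._w)
        )

    def __repr__(self) -> str:
        return f"CrossImpactMatrix(n_goals={self.n_goals}, n_links={self.n_links})"

    # -- conversions ---------------------------------------------------------

    def iter_scores(self) -> Iterator[InteractionScore]:
        """Yield all n(n-1) links in registry order (row-major)."""
        ids = self.goals
        for i, src in enumerate(ids):
            for j, tgt in enumerate(ids):
                if i != j:
                    yield InteractionScore(src, tgt, int(self._w[i, j]))

    def to_frame(self) -> pd.DataFrame:
        """Goals x goals DataFrame (Int64) with pd.NA on the diagonal."""
        data = self._w.astype(object)
        for i in range(self.n_goals):
            data[i, i] = None
        frame = pd.DataFrame(data, index=self.goals, columns=self.goals)
        return frame.astype("Int64")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, registry: GoalRegistry | None = None
    ) -> "CrossImpactMatrix":
        """Build from a square DataFrame; diagonal entries must be NA or 0."""
        if list(frame.index) != list(frame.columns):
            raise ScoreRangeError("matrix frame must have identical index and columns")
        registry = registry or GoalRegistry([str(g) for g in frame.index])
        values = frame.to_numpy(dtype="object")
        n = len(frame)
        w = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(n):
                cell = values[i, j]
                if i == j:
                    continue
                if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell is pd.NA:
                    raise IncompleteMatrixError(
                        f"missing score for pair ({frame.index[i]!r}, {frame.columns[j]!r})",
                        missing=[(str(frame.index[i]), str(frame.columns[j]))],
                    )
                w[i, j] = validate_score(cell)
        return cls(registry, w)


def build_matrix(
    goals: GoalRegistry | Sequence[str],
    scores: Iterable[InteractionScore],
) -> CrossImpactMatrix:
    """Assemble a complete matrix from a list of scored pairs.

    Every ordered off-diagonal pair must appear exactly once; the score list
    may arrive in any order (the result is order-insensitive). Duplicate
    pairs, unknown goals, self-pairs and out-of-range scores each raise a
    distinct validation error; missing pairs are all reported by id pair.
    """
    registry = goals if isinstance(goals, GoalRegistry) else GoalRegistry(list(goals))
    n = len(registry)
    w = np.zeros((n, n), dtype=np.int64)
    seen = np.zeros((n, n), dtype=bool)
    for s in scores:
        i = registry.index(s.source)  # raises UnknownGoalError
        j = registry.index(s.target)
        if i == j:
            raise SelfInteractionError(
                f"self-interaction {s.source!r} not allowed"
            )
        if seen[i, j]:
            raise DuplicateInteractionError(
                f"pair ({s.source!r}, {s.target!r}) scored more than once"
            )
        seen[i, j] = True
        w[i, j] = validate_score(s.score)
    np.fill_diagonal(seen, True)
    if not seen.all():
        ids = registry.ids
        missing = [
            (ids[i], ids[j]) for i, j in zip(*np.nonzero(~seen))
        ]
        raise IncompleteMatrixError(
            f"{len(missing)} missing pair(s): {missing[:10]}"
            + ("..." if len(missing) > 10 else ""),
            missing=missing,
        )
    return CrossImpactMatrix(registry, w)
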