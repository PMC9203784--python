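"""Interaction classification and matrix composition summaries.

An interaction is a *synergy* (positive score), a *trade-off* (negative
score) or *neutral* (zero). The composition summary reports counts and
integer percentages of each class across all n(n-1) links of a matrix.

Percentages are rounded half away from zero to the nearest integer; no
largest-remainder correction is applied, so the three rounded percentages may
sum to 99, 100 or 101 (the exact pre-rounding shares always sum to 100).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError
from .matrix import CrossImpactMatrix
from .scale import validate_score


def interaction_count(n_goals: int) -> int:
    """Number of ordered pairwise interactions among n goals: n(n-1)."""
    if not isinstance(n_goals, (int, np.integer)) or n_goals < 2:
        raise ConfigError(f"need an integer n_goals >= 2, got {n_goals!r}")
    return int(n_goals) * (int(n_goals) - 1)


def classify_score(score: int) -> str:
    """Sign classification of a scale score: 'positive', 'negative' or 'zero'."""
    value = validate_score(score)
    if value > 0:
        return "positive"
    if value < 0:
        return "negative"
    return "zero"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MatrixSummary:
    """Composition of a cross-impact matrix by interaction sign."""

    n_goals: int
    n_interactions: int
    count_positive: int
    count_negative: int
    count_zero: int
    pct_positive: int
    pct_negative: int
    pct_zero: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_tsv(self) -> str:
        """One header line plus one value line, tab-separated."""
        d = self.to_dict()
        keys = list(d)
        return (
            "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"
        )


def summarize_matrix(M: CrossImpactMatrix) -> MatrixSummary:
    """Count and percentage of positive / negative / zero interactions."""
    w = M.values()
    off = ~np.eye(M.n_goals, dtype=bool)
    cells = w[off]
    n = cells.size
    pos = int((cells > 0).sum())
    neg = int((cells < 0).sum())
    zero = int((cells == 0).sum())
    return MatrixSummary(
        n_goals=M.n_goals,
        n_interactions=n,
        count_positive=pos,
        count_negative=neg,
        count_zero=zero,
        pct_positive=round_half_away(100 * pos / n),
        pct_negative=round_half_away(100 * neg / n),
        pct_zero=round_half_away(100 * zero / n),
    )


def strength_table(M: CrossImpactMatrix) -> dict[int, int]:
    """Debug tally: number of links at each score value -3..+3."""
    w = M.values()
    off = ~np.eye(M.n_goals, dtype=bool)
    cells = w[off]
    return {s: int((cells == s).sum()) for s in range(-3, 4)}
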