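"""Exception hierarchy for validation failures.

Every error subclasses :class:`CrossImpactError` (itself a ``ValueError``)
so callers can catch the whole family, while the CLI maps each subclass to a
machine-readable error code.
"""

from __future__ import annotations


class CrossImpactError(ValueError):
    """Base class for all validation errors raised by this package."""

    #: short machine-readable code, overridden by subclasses
    code = "error"


class UnknownLabelError(CrossImpactError):
    """A qualitative scale label is not on the seven-point scale."""

    code = "unknown-label"


class UnknownGoalError(CrossImpactError):
    """A goal id (or alias) is not in the registry / matrix."""

    code = "unknown-goal"


class ScoreRangeError(CrossImpactError):
    """A score falls outside the integer scale -3..+3 (or is fractional)."""

    code = "score-out-of-range"


class SelfInteractionError(CrossImpactError):
    """A score was supplied for a goal's influence on itself."""

    code = "self-interaction"


class DuplicateInteractionError(CrossImpactError):
    """The same ordered (source, target) pair was scored twice."""

    code = "duplicate-pair"


class IncompleteMatrixError(CrossImpactError):
    """Off-diagonal cells are missing; ``missing`` lists the id pairs."""

    code = "incomplete-matrix"

    def __init__(self, message: str, missing: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.missing = missing or []


class MatrixFormatError(CrossImpactError):
    """A matrix CSV is malformed; carries the 1-based row/column location."""

    code = "matrix-format"

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class InsufficientOverlapError(CrossImpactError):
    """Two indicator series share fewer observation years than required."""

    code = "insufficient-overlap"


class ConsensusError(CrossImpactError):
    """Consensus resolution failed (e.g. manual rule without a decision)."""

    code = "consensus"


class ConfigError(CrossImpactError):
    """A generator or CLI configuration is invalid."""

    code = "config"
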