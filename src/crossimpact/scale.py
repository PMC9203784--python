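"""The seven-point cross-impact scale.

Interactions between goals are scored on the Weimer-Jehle seven-point scale:
consecutive integers from -3 (strongly restricting) through 0 (no influence)
to +3 (strongly promoting). The scale is the only place qualitative labels
and integer scores meet; everything downstream works on integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import ScoreRangeError, UnknownLabelError

SCORE_MIN = -3
SCORE_MAX = 3

_CANONICAL_LABELS: dict[str, int] = {
    "strongly restricting": -3,
    "moderately restricting": -2,
    "weakly restricting": -1,
    "no influence": 0,
    "weakly promoting": 1,
    "moderately promoting": 2,
    "strongly promoting": 3,
}

# verb-form and shorthand synonyms accepted on input, never emitted
_DEFAULT_SYNONYMS: dict[str, str] = {
    "strongly restrict": "strongly restricting",
    "moderately restrict": "moderately restricting",
    "weakly restrict": "weakly restricting",
    "none": "no influence",
    "no direct influence": "no influence",
    "weakly promote": "weakly promoting",
    "moderately promote": "moderately promoting",
    "strongly promote": "strongly promoting",
}


@dataclass(frozen=True)
class ScaleDefinition:
    """Bijective mapping between the seven qualitative labels and -3..+3.

    Parameters
    ----------
    labels
        Ordered mapping label -> score. Must contain exactly seven entries
        whose scores are the consecutive integers -3..+3.
    synonyms
        Optional alternative spellings, each mapping to a canonical label.
    """

    labels: Mapping[str, int] = field(
        default_factory=lambda: MappingProxyType(dict(_CANONICAL_LABELS))
    )
    synonyms: Mapping[str, str] = field(
        default_factory=lambda: MappingProxyType(dict(_DEFAULT_SYNONYMS))
    )

    def __post_init__(self) -> None:
        scores = sorted(self.labels.values())
        if scores != list(range(SCORE_MIN, SCORE_MAX + 1)):
            raise ScoreRangeError(
                "scale must map exactly seven labels onto the consecutive "
                f"integers {SCORE_MIN}..{SCORE_MAX}, got scores {scores}"
            )
        for syn, canon in self.synonyms.items():
            if canon not in self.labels:
                raise UnknownLabelError(
                    f"synonym {syn!r} maps to unknown label {canon!r}"
                )

    def label_to_score(self, label: str) -> int:
        """Map a qualitative label (case-insensitive) to its integer score."""
        key = " ".join(label.strip().lower().split())
        key = self.synonyms.get(key, key)
        try:
            return self.labels[key]
        except KeyError:
            raise UnknownLabelError(
                f"unknown scale label {label!r}; expected one of "
                f"{sorted(self.labels)}"
            ) from None

    def score_to_label(self, score: int) -> str:
        """Inverse of :meth:`label_to_score` on the canonical labels."""
        validate_score(score)
        for label, value in self.labels.items():
            if value == score:
                return label
        raise AssertionError("unreachable: scale is bijective")


#: The default seven-point scale used throughout the package.
DEFAULT_SCALE = ScaleDefinition()


def label_to_score(label: str, scale: ScaleDefinition = DEFAULT_SCALE) -> int:
    """Convenience wrapper over :meth:`ScaleDefinition.label_to_score`."""
    return scale.label_to_score(label)


def score_to_label(score: int, scale: ScaleDefinition = DEFAULT_SCALE) -> str:
    """Convenience wrapper over :meth:`ScaleDefinition.score_to_label`."""
    return scale.score_to_label(score)


def validate_score(score: int) -> int:
    """Check that *score* is an integer in -3..+3 and return it.

    Fractional weights are rejected: the whole pipeline operates on the
    integer scale, so exact integer arithmetic holds end to end.
    """
    if isinstance(score, bool) or not float(score).is_integer():
        raise ScoreRangeError(f"score must be an integer, got {score!r}")
    value = int(score)
    if not SCORE_MIN <= value <= SCORE_MAX:
        raise ScoreRangeError(
            f"score {value} outside the seven-point scale "
            f"{SCORE_MIN}..{SCORE_MAX}"
        )
    return value
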