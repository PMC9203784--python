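"""Multi-group scoring, cross-verification and consensus resolution.

In a scoring workshop, breakout groups score (possibly overlapping) subsets
of the goal pairs; groups then double-check their own scoring and verify a
set of pairs originally scored by another group. Pairs on which groups
disagree are listed as discrepancies and resolved — in the real protocol by
plenary consensus (the ``manual`` rule, driven by an explicit decisions
table), or for simulation by a ``median`` or ``rounded-mean`` rule.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .classification import round_half_away
from .errors import ConsensusError, DuplicateInteractionError
from .goals import GoalRegistry
from .matrix import InteractionScore
from .scale import validate_score

RULES = ("manual", "median", "rounded-mean")


@dataclass(frozen=True)
class GroupScoreSet:
    """Scores produced by one breakout group (any subset of the pairs)."""

    group_id: str
    scores: tuple[InteractionScore, ...]

    def __post_init__(self) -> None:
        pairs = [(s.source, s.target) for s in self.scores]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise DuplicateInteractionError(
                f"group {self.group_id!r} scored pair(s) {dupes} more than once"
            )

    def as_dict(self) -> dict[tuple[str, str], int]:
        return {(s.source, s.target): s.score for s in self.scores}


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One pair scored differently by at least two groups."""

    source: str
    target: str
    group_scores: Mapping[str, int]
    max_difference: int
    resolution: int | None = None
    note: str | None = None


def _pair_sort_key(registry: GoalRegistry | None):
    if registry is not None:
        return lambda pair: (registry.index(pair[0]), registry.index(pair[1]))

    def natural(gid: str):
        return (0, int(gid)) if gid.isdigit() else (1, gid)

    return lambda pair: (natural(pair[0]), natural(pair[1]))


def find_discrepancies(
    sets: Sequence[GroupScoreSet],
    threshold: int = 1,
    registry: GoalRegistry | None = None,
) -> list[DiscrepancyRecord]:
    """List pairs scored by >= 2 groups whose scores spread >= *threshold*.

    The default threshold of 1 flags any difference at all, matching a
    protocol in which every discrepancy goes to plenary discussion. Records
    are ordered by source then target (registry order when a registry is
    given, otherwise natural id order).
    """
    if len(sets) < 2:
        raise ConsensusError("discrepancy detection needs at least 2 groups")
    if threshold < 1:
        raise ConsensusError(f"threshold must be >= 1, got {threshold}")
    by_pair: dict[tuple[str, str], dict[str, int]] = {}
    for gs in sets:
        for s in gs.scores:
            by_pair.setdefault((s.source, s.target), {})[gs.group_id] = s.score
    records = []
    for pair in sorted(by_pair, key=_pair_sort_key(registry)):
        scores = by_pair[pair]
        if len(scores) < 2:
            continue
        spread = max(scores.values()) - min(scores.values())
        if spread >= threshold:
            records.append(
                DiscrepancyRecord(
                    source=pair[0],
                    target=pair[1],
                    group_scores=dict(scores),
                    max_difference=spread,
                )
            )
    return records


def _resolve_one(
    record: DiscrepancyRecord,
    rule: str,
    decisions: Mapping[tuple[str, str], int] | None,
) -> int:
    values = sorted(record.group_scores.values())
    if rule == "manual":
        key = (record.source, record.target)
        if decisions is None or key not in decisions:
            raise ConsensusError(
                f"manual rule: no decision supplied for pair {key}"
            )
        return validate_score(decisions[key])
    if rule == "median":
        med = statistics.median(values)
        return validate_score(round_half_away(med))
    if rule == "rounded-mean":
        return validate_score(round_half_away(statistics.mean(values)))
    raise ConsensusError(f"unknown rule {rule!r}; expected one of {RULES}")


def resolve_consensus(
    records: Iterable[DiscrepancyRecord],
    rule: str = "median",
    decisions: Mapping[tuple[str, str], int] | None = None,
) -> list[InteractionScore]:
    """Resolve each discrepant pair to one in-scale score tagged 'consensus'.

    ``median`` with an even count and a non-integral midpoint rounds half away
    from zero so the result stays on the integer scale; ``manual`` requires an
    explicit decision per pair and never auto-resolves silently.
    """
    out = []
    for rec in records:
        final = _resolve_one(rec, rule, decisions)
        out.append(
            InteractionScore(
                rec.source, rec.target, final, note_from(rec), provenance="consensus"
            )
        )
    return out


def note_from(rec: DiscrepancyRecord) -> str:
    groups = ", ".join(f"{g}:{v:+d}" for g, v in sorted(rec.group_scores.items()))
    return f"resolved from group scores [{groups}]"


def merge_group_scores(
    sets: Sequence[GroupScoreSet],
    rule: str = "median",
    threshold: int = 1,
    decisions: Mapping[tuple[str, str], int] | None = None,
    registry: GoalRegistry | None = None,
) -> list[InteractionScore]:
    """End-to-end reconciliation of all group score sets.

    Pairs scored identically (or by a single group) pass through unchanged
    with their original provenance dropped in favour of the group id;
    discrepant pairs are resolved under *rule*. The union of the group
    coverages determines the output coverage, so a complete union yields a
    buildable complete matrix.
    """
    if len(sets) < 2:
        raise ConsensusError("merging needs at least 2 groups")
    discrepant = {
        (r.source, r.target): r
        for r in find_discrepancies(sets, threshold=threshold, registry=registry)
    }
    agreed: dict[tuple[str, str], InteractionScore] = {}
    for gs in sets:
        for s in gs.scores:
            pair = (s.source, s.target)
            if pair in discrepant or pair in agreed:
                continue
            agreed[pair] = InteractionScore(
                s.source, s.target, s.score, s.motivation, provenance=gs.group_id
            )
    merged = list(agreed.values()) + resolve_consensus(
        discrepant.values(), rule=rule, decisions=decisions
    )
    merged.sort(
        key=lambda s: _pair_sort_key(registry)((s.source, s.target))
    )
    return merged
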