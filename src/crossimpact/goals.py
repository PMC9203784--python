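"""Goal registry: the nodes of the cross-impact network.

A registry is an ordered collection of goals with unique ids; ids are open
strings so the toolkit is not tied to any particular goal framework. Aliases
(e.g. "CH" for the child-health goal in the bundled Cambodia registry) resolve
to canonical ids on lookup.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import UnknownGoalError


@dataclass(frozen=True)
class GoalSpec:
    """One goal: a short id, a human-readable name and a definition."""

    id: str
    name: str = ""
    definition: str = ""
    aliases: tuple[str, ...] = ()


class GoalRegistry:
    """Ordered set of :class:`GoalSpec` with unique ids and alias lookup."""

    def __init__(self, goals: Iterable[GoalSpec | str]):
        specs: list[GoalSpec] = []
        for g in goals:
            specs.append(GoalSpec(id=g) if isinstance(g, str) else g)
        if len(specs) < 2:
            raise UnknownGoalError("a registry needs at least 2 goals")
        ids = [g.id for g in specs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise UnknownGoalError(f"duplicate goal ids in registry: {dupes}")
        self._goals: tuple[GoalSpec, ...] = tuple(specs)
        self._index: dict[str, int] = {g.id: i for i, g in enumerate(specs)}
        self._alias: dict[str, str] = {}
        for g in specs:
            for a in g.aliases:
                if a in self._index or a in self._alias:
                    raise UnknownGoalError(f"alias {a!r} collides with an existing id")
                self._alias[a] = g.id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self._goals)

    def resolve(self, goal: str) -> str:
        """Resolve an id or alias to the canonical goal id."""
        if goal in self._index:
            return goal
        if goal in self._alias:
            return self._alias[goal]
        raise UnknownGoalError(f"unknown goal id {goal!r}")

    def index(self, goal: str) -> int:
        return self._index[self.resolve(goal)]

    def __len__(self) -> int:
        return len(self._goals)

    def __iter__(self) -> Iterator[GoalSpec]:
        return iter(self._goals)

    def __contains__(self, goal: object) -> bool:
        return isinstance(goal, str) and (goal in self._index or goal in self._alias)

    def __getitem__(self, goal: str) -> GoalSpec:
        return self._goals[self.index(goal)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GoalRegistry) and self._goals == other._goals

    def __repr__(self) -> str:
        return f"GoalRegistry({list(self.ids)!r})"

    @classmethod
    def from_csv(cls, path: str | Path) -> "GoalRegistry":
        """Read a registry from CSV with columns id, name, definition[, aliases].

        ``aliases`` is a semicolon-separated list and may be absent or empty.
        """
        goals = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                aliases = tuple(
                    a for a in (row.get("aliases") or "").split(";") if a
                )
                goals.append(
                    GoalSpec(
                        id=row["id"].strip(),
                        name=(row.get("name") or "").strip(),
                        definition=(row.get("definition") or "").strip(),
                        aliases=aliases,
                    )
                )
        return cls(goals)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["id", "name", "definition", "aliases"])
            for g in self._goals:
                writer.writerow([g.id, g.name, g.definition, ";".join(g.aliases)])
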