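"""Readers and writers for matrices, scores, reports and graph exports.

Canonical matrix CSV dialect: UTF-8, comma-separated, LF line endings; first
row is ``goal`` followed by the goal ids; each following row is a goal id and
n cells; diagonal cells are written empty and read as empty or "NA"; all
other cells are integers on the seven-point scale. A semicolon-delimited
variant is accepted on read with a warning. ``write_matrix_csv`` followed by
``read_matrix_csv`` round-trips bit-exact.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import warnings
from pathlib import Path

import networkx as nx

from .errors import MatrixFormatError, SelfInteractionError
from .goals import GoalRegistry
from .matrix import CrossImpactMatrix, InteractionScore, build_matrix
from .scale import SCORE_MAX, SCORE_MIN

_NA_TOKENS = {"", "NA"}


def _bundled_registry_for(ids: list[str]) -> GoalRegistry | None:
    """Attach the bundled Cambodia registry (names, aliases) when the CSV
    header matches its goal ids exactly; otherwise build a bare registry."""
    from .synthetic import cambodia_goal_registry

    cambodia = cambodia_goal_registry()
    return cambodia if tuple(ids) == cambodia.ids else None


def read_matrix_csv(path: str | Path) -> CrossImpactMatrix:
    """Read a cross-impact matrix from CSV, with located format errors."""
    text = Path(path).read_text(encoding="utf-8")
    delimiter = ","
    first_line = text.splitlines()[0] if text.splitlines() else ""
    if ";" in first_line and "," not in first_line:
        warnings.warn(
            f"{path}: semicolon-delimited matrix accepted; the canonical "
            "dialect is comma-separated",
            stacklevel=2,
        )
        delimiter = ";"
    rows = list(csv.reader(_io.StringIO(text), delimiter=delimiter))
    if not rows or not rows[0] or rows[0][0].strip().lower() != "goal":
        raise MatrixFormatError(
            "malformed header: first cell must be 'goal'", row=1, column=1
        )
    ids = [c.strip() for c in rows[0][1:]]
    if len(ids) < 2:
        raise MatrixFormatError("header lists fewer than 2 goals", row=1)
    if len(rows) - 1 != len(ids):
        raise MatrixFormatError(
            f"expected {len(ids)} data rows for {len(ids)} goals, got {len(rows) - 1}"
        )
    registry = _bundled_registry_for(ids) or GoalRegistry(ids)
    scores = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or row[0].strip() not in ids:
            raise MatrixFormatError(
                f"row label {row[0]!r} is not a goal from the header", row=r, column=1
            )
        src = row[0].strip()
        if len(row) - 1 != len(ids):
            raise MatrixFormatError(
                f"row {src!r} has {len(row) - 1} cells, expected {len(ids)}", row=r
            )
        for c, cell in enumerate(row[1:], start=2):
            tgt = ids[c - 2]
            token = cell.strip()
            if src == tgt:
                if token not in _NA_TOKENS:
                    raise SelfInteractionError(
                        f"self-interaction not allowed: diagonal cell "
                        f"({src!r}, {tgt!r}) at row {r}, column {c} must be "
                        f"empty or NA, got {token!r}"
                    )
                continue
            if token in _NA_TOKENS:
                raise MatrixFormatError(
                    f"missing score for pair ({src!r}, {tgt!r})", row=r, column=c
                )
            try:
                value = int(token)
            except ValueError:
                raise MatrixFormatError(
                    f"non-integer cell {token!r} at row {r}, column {c}",
                    row=r,
                    column=c,
                ) from None
            if not SCORE_MIN <= value <= SCORE_MAX:
                raise MatrixFormatError(
                    f"score {value} out of range {SCORE_MIN}..{SCORE_MAX} "
                    f"at row {r}, column {c}",
                    row=r,
                    column=c,
                )
            scores.append(InteractionScore(src, tgt, value))
    return build_matrix(registry, scores)


def matrix_to_csv_text(M: CrossImpactMatrix) -> str:
    """Canonical matrix CSV text (empty diagonal, LF endings)."""
    lines = ["goal," + ",".join(M.goals)]
    w = M.values()
    for i, src in enumerate(M.goals):
        cells = [
            "" if i == j else str(int(w[i, j])) for j in range(M.n_goals)
        ]
        lines.append(src + "," + ",".join(cells))
    return "\n".join(lines) + "\n"


def write_matrix_csv(M: CrossImpactMatrix, path: str | Path) -> None:
    """Write the canonical matrix CSV; re-reading round-trips bit-exact."""
    Path(path).write_text(matrix_to_csv_text(M), encoding="utf-8", newline="\n")


def read_group_scores_csv(path: str | Path) -> list[InteractionScore]:
    """Read scores from CSV with columns source, target, score[, motivation]."""
    scores = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            scores.append(
                InteractionScore(
                    source=row["source"].strip(),
                    target=row["target"].strip(),
                    score=int(row["score"]),
                    motivation=(row.get("motivation") or None),
                )
            )
    return scores


def read_decisions_csv(path: str | Path) -> dict[tuple[str, str], int]:
    """Read manual consensus decisions: source, target, final_score[, note]."""
    decisions = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            decisions[(row["source"].strip(), row["target"].strip())] = int(
                row["final_score"]
            )
    return decisions


def write_scores_csv(scores: list[InteractionScore], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source", "target", "score", "motivation", "provenance"])
        for s in scores:
            writer.writerow(
                [s.source, s.target, s.score, s.motivation or "", s.provenance or ""]
            )


def export_edge_list(
    M: CrossImpactMatrix, path: str | Path | None = None, include_zeros: bool = False
) -> str:
    """TSV edge list (source, target, weight) in registry row-major order.

    Zero-weight links are omitted by default — a drawn network shows
    influences, not their absence; ``include_zeros`` emits all n(n-1) rows.
    """
    lines = ["source\ttarget\tweight"]
    for s in M.iter_scores():
        if s.score != 0 or include_zeros:
            lines.append(f"{s.source}\t{s.target}\t{s.score}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    return text


def to_graph(M: CrossImpactMatrix, include_zeros: bool = False) -> nx.DiGraph:
    """networkx DiGraph with integer ``weight`` edge attributes."""
    g = nx.DiGraph()
    g.add_nodes_from(M.goals)
    for s in M.iter_scores():
        if s.score != 0 or include_zeros:
            g.add_edge(s.source, s.target, weight=int(s.score))
    return g


def export_graphml(
    M: CrossImpactMatrix, path: str | Path, include_zeros: bool = False
) -> None:
    nx.write_graphml(to_graph(M, include_zeros=include_zeros), str(path))


def file_checksum(path: str | Path) -> str:
    """sha256 hex digest of a file, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
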