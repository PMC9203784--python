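"""Model/Results interface over the cross-impact analysis.

:class:`CrossImpactModel` wraps a validated matrix plus analysis options;
:meth:`CrossImpactModel.fit` evaluates the network and returns a
:class:`CrossImpactResults` carrying the per-goal influence table, rankings,
the pairwise second-order matrix, the composition summary, and a text
``summary()``. The computation is deterministic and exact (integer
arithmetic throughout), so "fitting" here means evaluating the network
statistics, not estimating free parameters.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .classification import MatrixSummary, summarize_matrix
from .goals import GoalRegistry
from .influence import (
    FocalPerspective,
    focal_perspective,
    influence_table,
    rank_goals,
    second_order_matrix,
)
from .io import file_checksum, read_matrix_csv
from .matrix import CrossImpactMatrix, InteractionScore, build_matrix


class CrossImpactModel:
    """Cross-impact network model built from a complete score matrix.

    Parameters
    ----------
    matrix
        A validated :class:`CrossImpactMatrix`.
    exclude_backlink
        If True, the second-order term of a goal's total influence drops the
        backlink contribution w_gj * w_jg (the neighbour's influence straight
        back onto g). The default keeps it, reading the total-influence
        formula literally.
    """

    def __init__(self, matrix: CrossImpactMatrix, exclude_backlink: bool = False):
        self.matrix = matrix
        self.exclude_backlink = exclude_backlink

    @classmethod
    def from_scores(
        cls,
        goals: GoalRegistry | list[str],
        scores: list[InteractionScore],
        **kwargs,
    ) -> "CrossImpactModel":
        return cls(build_matrix(goals, scores), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CrossImpactModel":
        """Build from a goals x goals DataFrame with an NA diagonal."""
        return cls(CrossImpactMatrix.from_frame(frame), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CrossImpactModel":
        model = cls(read_matrix_csv(path), **kwargs)
        model._source = str(path)
        return model

    def fit(self) -> "CrossImpactResults":
        """Evaluate all network statistics and return the results object."""
        return CrossImpactResults(self)


class CrossImpactResults:
    """Influence statistics, rankings and composition of a fitted model."""

    def __init__(self, model: CrossImpactModel):
        self.model = model
        M = model.matrix
        #: per-goal table: degrees, first/second/total influence, ranks, shift
        self.influence: pd.DataFrame = influence_table(
            M, exclude_backlink=model.exclude_backlink
        )
        #: pairwise second-order influence (diagonal = feedback loops)
        self.second_order: pd.DataFrame = second_order_matrix(M)
        #: sign composition of the matrix
        self.composition: MatrixSummary = summarize_matrix(M)

    @property
    def matrix(self) -> CrossImpactMatrix:
        return self.model.matrix

    def ranking(self, order: str = "total") -> pd.DataFrame:
        """Goals sorted by descending first-order or total influence."""
        return rank_goals(
            self.matrix, order=order, exclude_backlink=self.model.exclude_backlink
        )

    def focal(self, goal: str) -> FocalPerspective:
        """The network from the perspective of one goal."""
        return focal_perspective(self.matrix, goal)

    def to_report(self, provenance: dict | None = None) -> dict:
        """Self-contained JSON-serialisable analysis report.

        Re-deriving the report from the same matrix reproduces it exactly;
        the provenance block (input path/checksum, seed, version) makes a
        report reproducible from its inputs alone.
        """
        prov = {"tool": "crossimpact", "version": _version}
        source = getattr(self.model, "_source", None)
        if source is not None:
            prov["input"] = source
            prov["input_sha256"] = file_checksum(source)
        if provenance:
            prov.update(provenance)
        influence = self.influence.reset_index().to_dict(orient="records")
        return {
            "provenance": prov,
            "options": {"exclude_backlink": self.model.exclude_backlink},
            "summary": self.composition.to_dict(),
            "influence": influence,
            "ranking_first": list(self.ranking("first").index),
            "ranking_total": list(self.ranking("total").index),
        }

    def influence_csv(self) -> str:
        """Flat CSV of the per-goal influence report."""
        cols = [
            "goal", "out_degree", "in_degree", "first_order",
            "second_order_total", "total", "rank_first", "rank_total",
            "rank_shift",
        ]
        frame = self.influence.reset_index()[cols]
        return frame.to_csv(index=False, lineterminator="\n")

    def summary(self) -> str:
        """Human-readable summary table (composition + ranked influences)."""
        comp = self.composition
        lines = [
            "Cross-impact network analysis",
            "=" * 64,
            f"goals: {comp.n_goals}    interactions: {comp.n_interactions}",
            (
                f"positive: {comp.count_positive} ({comp.pct_positive}%)   "
                f"negative: {comp.count_negative} ({comp.pct_negative}%)   "
                f"zero: {comp.count_zero} ({comp.pct_zero}%)"
            ),
            "-" * 64,
            f"{'goal':>6} {'out':>6} {'in':>6} {'total':>8} "
            f"{'rank1st':>8} {'rankTot':>8} {'shift':>6}",
        ]
        for goal, row in self.ranking("total").iterrows():
            lines.append(
                f"{goal:>6} {row.out_degree:>6d} {row.in_degree:>6d} "
                f"{row.total:>8d} {row.rank_first:>8d} {row.rank_total:>8d} "
                f"{row.rank_shift:>+6d}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"CrossImpactResults(n_goals={self.matrix.n_goals}, "
            f"n_links={self.matrix.n_links})"
        )
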