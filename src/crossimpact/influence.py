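"""First-order, second-order and total network influence.

The cross-impact matrix is read as a weighted directed graph. Three layers of
influence are computed, all in exact integer arithmetic:

* **First-order influence** of goal g is its weighted out-degree
  D_g^Out = sum_j w_gj (the row sum); the column sum D_g^In measures how much
  g is influenced by the rest of the network.

* **Second-order influence** of goal A on goal D aggregates all directed
  length-2 paths:  I2(A, D) = sum_i w_Ai * w_iD  with i ranging over the
  goals connecting A and D (i is never A or D for A != D; for A = D the sum
  over i != A is the *feedback-loop strength* — how much progress on A
  indirectly reinforces itself through the network).

* **Total (net) influence** of g on the network combines both layers:

      I_g^Total = D_g^Out + sum_{j != g} w_gj * D_j^Out

  implemented literally: D_j^Out includes the backlink w_jg unless
  ``exclude_backlink`` is set (both variants exposed; literal is the default).

Ranks use competition ranking (1, 1, 3); ties keep registry order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CrossImpactMatrix

__all__ = [
    "weighted_degree",
    "second_order_influence",
    "second_order_matrix",
    "total_influence",
    "influence_table",
    "rank_goals",
    "focal_perspective",
    "FocalPerspective",
]


def weighted_degree(M: CrossImpactMatrix, g: str, direction: str = "out") -> int:
    """Weighted out-degree (row sum) or in-degree (column sum) of goal *g*."""
    i = M.registry.index(g)
    w = M.values()
    if direction == "out":
        return int(w[i, :].sum())
    if direction == "in":
        return int(w[:, i].sum())
    raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")


def second_order_matrix(M: CrossImpactMatrix) -> pd.DataFrame:
    """All pairwise second-order influences I2(A, D), including A = D.

    With a structurally zero diagonal, the matrix product W @ W realises the
    path sum exactly: the i = A and i = D terms vanish because w_AA = w_DD = 0,
    and the diagonal entries are the feedback-loop strengths. Bilinear in the
    weights: scaling all w by c scales every entry by c**2.
    """
    w = M.values()
    s = w @ w
    return pd.DataFrame(s, index=M.goals, columns=M.goals)


def second_order_influence(M: CrossImpactMatrix, A: str, D: str) -> int:
    """Second-order influence of *A* on *D* (A = D gives feedback strength)."""
    i = M.registry.index(A)
    j = M.registry.index(D)
    w = M.values()
    return int(w[i, :] @ w[:, j])


def total_influence(
    M: CrossImpactMatrix, g: str, exclude_backlink: bool = False
) -> int:
    """Total net influence of *g*: out-degree plus out-degree-weighted paths."""
    i = M.registry.index(g)
    w = M.values()
    out = w.sum(axis=1)
    second = int(w[i, :] @ out)
    if exclude_backlink:
        second -= int(w[i, :] @ w[:, i])  # drop the w_jg backlink inside D_j^Out
    return int(out[i]) + second


def influence_table(
    M: CrossImpactMatrix, exclude_backlink: bool = False
) -> pd.DataFrame:
    """Per-goal influence report.

    Columns: out_degree, in_degree, first_order (= out_degree),
    second_order_total, total (= first + second), rank_first, rank_total,
    rank_shift (= rank_first - rank_total; positive means the goal climbs
    once indirect effects are counted).
    """
    w = M.values()
    out = w.sum(axis=1)
    inn = w.sum(axis=0)
    second = w @ out
    if exclude_backlink:
        second = second - np.einsum("ij,ji->i", w, w)
    total = out + second
    table = pd.DataFrame(
        {
            "out_degree": out,
            "in_degree": inn,
            "first_order": out,
            "second_order_total": second,
            "total": total,
        },
        index=pd.Index(M.goals, name="goal"),
    )
    table["rank_first"] = _competition_rank(table["first_order"].to_numpy())
    table["rank_total"] = _competition_rank(table["total"].to_numpy())
    table["rank_shift"] = table["rank_first"] - table["rank_total"]
    return table


def _competition_rank(values: np.ndarray) -> np.ndarray:
    """Descending competition rank: 1 + number of strictly larger values."""
    return 1 + (values[None, :] > values[:, None]).sum(axis=1)


def rank_goals(
    M: CrossImpactMatrix, order: str = "total", exclude_backlink: bool = False
) -> pd.DataFrame:
    """Goals sorted by descending influence with rank-shift annotations.

    ``order`` selects the sort key ('first' or 'total'); tie groups keep the
    goal registry order, so the listing is fully deterministic.
    """
    if order not in ("first", "total"):
        raise ValueError(f"order must be 'first' or 'total', got {order!r}")
    table = influence_table(M, exclude_backlink=exclude_backlink)
    key = "first_order" if order == "first" else "total"
    # stable mergesort keeps registry order inside tie groups
    return table.sort_values(key, ascending=False, kind="mergesort")


@dataclass(frozen=True)
class FocalPerspective:
    """The network as seen from one focal goal.

    Four vectors over all *other* goals plus the feedback-loop strength:
    first-order outgoing (the goal's matrix row), first-order incoming (its
    column), second-order outgoing I2(g -> D) and incoming I2(A -> g).
    """

    goal: str
    first_order_out: pd.Series
    first_order_in: pd.Series
    second_order_out: pd.Series
    second_order_in: pd.Series
    feedback: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "first_order_out": self.first_order_out,
                "first_order_in": self.first_order_in,
                "second_order_out": self.second_order_out,
                "second_order_in": self.second_order_in,
            }
        )


def focal_perspective(M: CrossImpactMatrix, g: str) -> FocalPerspective:
    """Direct and second-order influence to and from one focal goal."""
    gid = M.registry.resolve(g)
    i = M.registry.index(gid)
    w = M.values()
    s = w @ w
    others = [x for x in M.goals if x != gid]
    keep = [k for k in range(M.n_goals) if k != i]
    return FocalPerspective(
        goal=gid,
        first_order_out=pd.Series(w[i, keep], index=others, name="first_order_out"),
        first_order_in=pd.Series(w[keep, i], index=others, name="first_order_in"),
        second_order_out=pd.Series(s[i, keep], index=others, name="second_order_out"),
        second_order_in=pd.Series(s[keep, i], index=others, name="second_order_in"),
        feedback=int(s[i, i]),
    )
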