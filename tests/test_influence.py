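"""Influence computations checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossimpact import (
    CrossImpactMatrix,
    GoalRegistry,
    focal_perspective,
    influence_table,
    rank_goals,
    second_order_influence,
    second_order_matrix,
    total_influence,
    weighted_degree,
)
from crossimpact.errors import UnknownGoalError
from crossimpact.synthetic import cambodia_child_health_matrix

from conftest import random_matrix


# -- independent oracles -----------------------------------------------------

def brute_second_order(M, a, d):
    """Enumerate every directed length-2 path a -> i -> d by hand."""
    total = 0
    for i in M.goals:
        if i in (a, d):
            continue
        total += M.weight(a, i) * M.weight(i, d)
    return total


def literal_total(M, g):
    """Direct substitution: D_g_out + sum_{j != g} w_gj * D_j_out."""
    out = {x: sum(M.weight(x, y) for y in M.goals if y != x) for x in M.goals}
    return out[g] + sum(M.weight(g, j) * out[j] for j in M.goals if j != g)


# -- toy-matrix examples -----------------------------------------------------

def test_toy_degrees(toy_matrix):
    assert weighted_degree(toy_matrix, "A", "out") == 3
    assert weighted_degree(toy_matrix, "A", "in") == 0
    assert weighted_degree(toy_matrix, "C", "in") == 4


def test_toy_second_order_single_path(toy_matrix):
    assert second_order_influence(toy_matrix, "A", "C") == 6  # 2 * 3


def test_toy_feedback_null(toy_matrix):
    assert second_order_influence(toy_matrix, "A", "A") == 0


def test_toy_total_influence(toy_matrix):
    assert total_influence(toy_matrix, "A") == 9  # 3 + (2*3 + 1*0)
    assert total_influence(toy_matrix, "C") == 0


def test_toy_ranking(toy_matrix):
    ranked = rank_goals(toy_matrix, order="total")
    assert list(ranked.index) == ["A", "B", "C"]
    assert ranked["total"].tolist() == [9, 3, 0]
    assert ranked["rank_total"].tolist() == [1, 2, 3]


def test_unknown_goal_raises(toy_matrix):
    with pytest.raises(UnknownGoalError):
        weighted_degree(toy_matrix, "Z")


def test_all_zero_matrix_full_tie():
    m = CrossImpactMatrix(GoalRegistry(["A", "B", "C"]), np.zeros((3, 3), dtype=int))
    table = influence_table(m)
    assert table["rank_first"].tolist() == [1, 1, 1]
    assert table["rank_total"].tolist() == [1, 1, 1]


def test_tie_groups_keep_registry_order():
    # B and C tie; ranking must list B before C and give both rank 2
    w = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
    m = CrossImpactMatrix(GoalRegistry(["A", "B", "C"]), w)
    ranked = rank_goals(m, order="first")
    assert list(ranked.index) == ["A", "B", "C"]
    assert ranked["rank_first"].tolist() == [1, 2, 2]


# -- child-health fixture ----------------------------------------------------

def test_child_health_row_and_column_sums(child_health_matrix):
    assert weighted_degree(child_health_matrix, "CH", "out") == 16
    assert weighted_degree(child_health_matrix, "CH", "in") == 29


def test_child_health_feedback_loop_positive(child_health_matrix):
    fb = second_order_influence(child_health_matrix, "3", "3")
    assert fb == 30
    assert fb > 0


def test_child_health_first_order_entries(child_health_matrix):
    persp = focal_perspective(child_health_matrix, "CH")
    assert persp.first_order_out["1"] == 3   # strongly promotes no-poverty
    assert persp.first_order_in["6"] == 3    # strongly influenced by water/sanitation
    assert persp.first_order_out["15"] == 0  # no direct influence on life on land
    assert persp.feedback == 30


def test_child_health_stats_invariant_under_completion():
    """CH's row/column statistics depend only on its own row and column."""
    for seed in (1, 7, 123):
        m = cambodia_child_health_matrix(seed=seed)
        assert weighted_degree(m, "3", "out") == 16
        assert weighted_degree(m, "3", "in") == 29
        assert second_order_influence(m, "3", "3") == 30


# -- property tests against the oracles --------------------------------------

@settings(deadline=None, max_examples=40)
@given(
    n=st.integers(min_value=2, max_value=8),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_second_order_matches_bruteforce(n, seed):
    m = random_matrix(np.random.default_rng(seed), n)
    s = second_order_matrix(m)
    for a in m.goals:
        for d in m.goals:
            if a == d:
                continue
            expected = brute_second_order(m, a, d)
            assert second_order_influence(m, a, d) == expected
            assert s.loc[a, d] == expected


@settings(deadline=None, max_examples=40)
@given(
    n=st.integers(min_value=2, max_value=8),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_total_influence_matches_literal_formula(n, seed):
    m = random_matrix(np.random.default_rng(seed), n)
    for g in m.goals:
        assert total_influence(m, g) == literal_total(m, g)


@settings(deadline=None, max_examples=20)
@given(
    n=st.integers(min_value=2, max_value=6),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    c=st.sampled_from([-3, -1, 2, 3]),
)
def test_linearity_in_the_weights(n, seed, c):
    """First-order scales by c; second-order entries scale by c**2."""
    m = random_matrix(np.random.default_rng(seed), n)
    w = np.clip(m.values(), -1, 1)  # keep c*w on the scale
    m1 = CrossImpactMatrix(m.registry, w)
    mc = CrossImpactMatrix(m.registry, c * w)
    for g in m.goals:
        assert weighted_degree(mc, g) == c * weighted_degree(m1, g)
    assert (
        second_order_matrix(mc).to_numpy()
        == c * c * second_order_matrix(m1).to_numpy()
    ).all()


@settings(deadline=None, max_examples=25)
@given(
    n=st.integers(min_value=2, max_value=7),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_permutation_invariance(n, seed):
    """Relabelling goals permutes every per-goal statistic identically."""
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n)
    perm = rng.permutation(n)
    ids = list(m.goals)
    permuted_ids = [ids[i] for i in perm]
    w = m.values()[np.ix_(perm, perm)]
    mp = CrossImpactMatrix(GoalRegistry(permuted_ids), w)
    base = influence_table(m)
    moved = influence_table(mp)
    for g in ids:
        for col in ("out_degree", "in_degree", "total", "rank_total"):
            assert base.loc[g, col] == moved.loc[g, col]


@settings(deadline=None, max_examples=30)
@given(
    n=st.integers(min_value=2, max_value=8),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_out_in_degree_sum_identity(n, seed):
    m = random_matrix(np.random.default_rng(seed), n)
    outs = [weighted_degree(m, g, "out") for g in m.goals]
    ins = [weighted_degree(m, g, "in") for g in m.goals]
    assert sum(outs) == sum(ins) == m.values().sum()


def test_total_reduces_to_first_order_when_neighbours_silent():
    """If every neighbour has zero out-degree, the second-order term vanishes."""
    w = np.array([[0, 2, 1], [0, 0, 0], [0, 0, 0]])
    m = CrossImpactMatrix(GoalRegistry(["A", "B", "C"]), w)
    for g in ("B", "C"):
        assert total_influence(m, "A") == weighted_degree(m, "A")


def test_exclude_backlink_variant():
    """Dropping backlinks removes exactly the feedback-loop term."""
    rng = np.random.default_rng(5)
    m = random_matrix(rng, 6)
    for g in m.goals:
        literal = total_influence(m, g)
        trimmed = total_influence(m, g, exclude_backlink=True)
        assert literal - trimmed == second_order_influence(m, g, g)


def test_structural_ranks_on_synthetic_matrix():
    from crossimpact.synthetic import MatrixGenConfig, generate_matrix

    m = generate_matrix(MatrixGenConfig(seed=11))
    for order in ("first", "total"):
        ranked = rank_goals(m, order=order)
        assert len(ranked) == 17
        col = "rank_first" if order == "first" else "rank_total"
        assert ranked[col].between(1, 17).all()
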