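import numpy as np
import pytest

from crossimpact import find_discrepancies, summarize_matrix, weighted_degree
from crossimpact.errors import ConfigError
from crossimpact.synthetic import (
    CHILD_HEALTH_ID,
    IndicatorGenConfig,
    MatrixGenConfig,
    cambodia_child_health_fixture,
    cambodia_child_health_matrix,
    cambodia_goal_registry,
    generate_group_scores,
    generate_indicator_series,
    generate_matrix,
)


def test_generated_matrix_structure():
    m = generate_matrix(MatrixGenConfig(seed=0))
    assert m.n_goals == 17
    assert m.n_links == 272
    w = m.values()
    off = ~np.eye(17, dtype=bool)
    assert w[off].min() >= -3 and w[off].max() <= 3


def test_degenerate_all_zero_config():
    cfg = MatrixGenConfig(n_goals=5, p_positive=0, p_negative=0, p_zero=1, seed=3)
    m = generate_matrix(cfg)
    assert (m.values() == 0).all()


def test_seed_reproducibility_and_divergence():
    a = generate_matrix(MatrixGenConfig(seed=123))
    b = generate_matrix(MatrixGenConfig(seed=123))
    c = generate_matrix(MatrixGenConfig(seed=124))
    assert a == b
    assert a != c


def test_invalid_simplex_rejected():
    with pytest.raises(ConfigError):
        MatrixGenConfig(p_positive=0.5, p_negative=0.5, p_zero=0.5)
    with pytest.raises(ConfigError):
        MatrixGenConfig(n_goals=1)


def test_generated_matrices_pass_validation():
    # CrossImpactMatrix construction validates range/diagonal; summarize covers it
    for seed in range(5):
        m = generate_matrix(MatrixGenConfig(n_goals=6, seed=seed))
        s = summarize_matrix(m)
        assert s.n_interactions == 30


def test_reciprocity_copies_mirror_cells():
    cfg = MatrixGenConfig(n_goals=8, reciprocity=1.0, seed=9)
    w = generate_matrix(cfg).values()
    assert (w == w.T).all()


def test_group_scores_zero_rate_identical_to_truth():
    truth = generate_matrix(MatrixGenConfig(n_goals=6, seed=1))
    sets = generate_group_scores(truth, disagreement_rate=0.0, seed=2)
    truth_scores = {(s.source, s.target): s.score for s in truth.iter_scores()}
    for gs in sets:
        assert gs.as_dict() == truth_scores
    assert find_discrepancies(sets) == []


def test_forced_perturbation_on_interior_scores():
    """rate=1, max_shift=1: every group score differs from truth by exactly 1
    wherever the truth score is interior (|score| < 3)."""
    cfg = MatrixGenConfig(
        n_goals=6, p_positive=1.0, p_negative=0.0, p_zero=0.0,
        magnitude_probs=(1.0, 0.0, 0.0), seed=4,
    )  # all truth scores are +1: interior
    truth = generate_matrix(cfg)
    sets = generate_group_scores(truth, disagreement_rate=1.0, max_shift=1, seed=5)
    truth_scores = {(s.source, s.target): s.score for s in truth.iter_scores()}
    for gs in sets:
        for pair, score in gs.as_dict().items():
            assert abs(score - truth_scores[pair]) == 1


def test_invalid_group_score_configs():
    truth = generate_matrix(MatrixGenConfig(n_goals=4, seed=0))
    with pytest.raises(ConfigError):
        generate_group_scores(truth, disagreement_rate=1.5)
    with pytest.raises(ConfigError):
        generate_group_scores(truth, disagreement_rate=0.1, max_shift=0)


def test_child_health_fixture_values():
    row, col = cambodia_child_health_fixture()
    assert len(row) == len(col) == 16
    assert sum(row.values()) == 16
    assert sum(col.values()) == 29
    assert row["15"] == 0
    assert row["1"] == 3 and row["4"] == 3 and row["8"] == 3
    assert col["6"] == 3 and col["11"] == 3
    assert sorted(v for v in col.values()) == sorted([3, 3] + [2] * 9 + [1] * 5)


def test_child_health_matrix_embeds_fixture():
    m = cambodia_child_health_matrix(seed=42)
    row, col = cambodia_child_health_fixture()
    for gid, score in row.items():
        assert m.weight(CHILD_HEALTH_ID, gid) == score
    for gid, score in col.items():
        assert m.weight(gid, CHILD_HEALTH_ID) == score
    assert weighted_degree(m, "CH", "out") == 16


def test_cambodia_registry():
    reg = cambodia_goal_registry()
    assert len(reg) == 17
    assert reg.resolve("CH") == "3"
    assert "17" not in reg  # partnerships goal excluded from the assessment
    assert reg["16"].name == "Peace, justice and strong institutions"


def test_indicator_generator_seeded_and_validated():
    cfg = IndicatorGenConfig(slope=-2.0, noise_sd=1.0, seed=7,
                             increase_is_progress=False)
    a = generate_indicator_series(cfg)
    b = generate_indicator_series(cfg)
    assert a.observations == b.observations
    assert list(a.observations) == [2000, 2005, 2010, 2015, 2020]
    with pytest.raises(ConfigError):
        IndicatorGenConfig(n_years=2)
    with pytest.raises(ConfigError):
        IndicatorGenConfig(noise_sd=-1)


def test_noiseless_generator_is_exactly_linear():
    cfg = IndicatorGenConfig(intercept=10, slope=2, noise_sd=0.0)
    s = generate_indicator_series(cfg)
    assert s.observations[2000] == 10
    assert s.observations[2010] == 10 + 2 * 10
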