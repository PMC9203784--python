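"""Seeded generators and bundled Cambodia fixtures.

The study's full 17-goal matrix is only distributed as supplementary data,
so the package ships (a) seeded generators producing matrices, group scores
and indicator series with the statistical structure the analysis assumes,
calibrated to the published composition (78% positive / 4% negative / 18%
zero interactions), and (b) the pieces of the Cambodia assessment that are
fully reconstructible: the goal registry, the child-health row and column of
the matrix, and the key-indicator table.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import GroupScoreSet
from .errors import ConfigError
from .goals import GoalRegistry
from .matrix import CrossImpactMatrix, InteractionScore
from .trends import IndicatorSeries

#: canonical id of the child-health goal in the bundled Cambodia registry
CHILD_HEALTH_ID = "3"

# calibration: published composition of the 272 scored interactions
DEFAULT_P_POSITIVE = 0.78
DEFAULT_P_NEGATIVE = 0.04
DEFAULT_P_ZERO = 0.18


def _data_path(name: str):
    return resources.files("crossimpact.data").joinpath(name)


@dataclass(frozen=True)
class MatrixGenConfig:
    """Configuration for random cross-impact matrices.

    Each off-diagonal cell is drawn i.i.d.: sign from (p_positive,
    p_negative, p_zero), magnitude of nonzero scores from
    ``magnitude_probs`` over {1, 2, 3} (uniform by default — the published
    composition fixes signs, not magnitudes). ``reciprocity`` optionally
    copies w_ij onto w_ji with the given probability, for sensitivity
    studies on non-independent matrices.
    """

    n_goals: int = 17
    p_positive: float = DEFAULT_P_POSITIVE
    p_negative: float = DEFAULT_P_NEGATIVE
    p_zero: float = DEFAULT_P_ZERO
    magnitude_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    reciprocity: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_goals < 2:
            raise ConfigError(f"n_goals must be >= 2, got {self.n_goals}")
        probs = (self.p_positive, self.p_negative, self.p_zero)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"(p_positive, p_negative, p_zero)={probs} is not a probability simplex"
            )
        mags = self.magnitude_probs
        if len(mags) != 3 or any(p < 0 for p in mags) or abs(sum(mags) - 1.0) > 1e-9:
            raise ConfigError(
                f"magnitude_probs {mags} must be 3 probabilities summing to 1"
            )
        if not 0.0 <= self.reciprocity <= 1.0:
            raise ConfigError(f"reciprocity must be in [0, 1], got {self.reciprocity}")


def generate_matrix(
    cfg: MatrixGenConfig, registry: GoalRegistry | None = None
) -> CrossImpactMatrix:
    """Draw a complete random matrix under *cfg* (seeded, reproducible)."""
    if registry is not None and len(registry) != cfg.n_goals:
        raise ConfigError(
            f"registry has {len(registry)} goals but config asks for {cfg.n_goals}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_goals
    signs = rng.choice(
        [1, -1, 0], size=(n, n), p=[cfg.p_positive, cfg.p_negative, cfg.p_zero]
    )
    mags = rng.choice([1, 2, 3], size=(n, n), p=list(cfg.magnitude_probs))
    w = signs * mags
    if cfg.reciprocity > 0:
        copy = rng.random((n, n)) < cfg.reciprocity
        iu = np.triu_indices(n, k=1)
        w.T[iu] = np.where(copy[iu], w[iu], w.T[iu])
    np.fill_diagonal(w, 0)
    registry = registry or GoalRegistry([f"G{i + 1}" for i in range(n)])
    return CrossImpactMatrix(registry, w)


def generate_group_scores(
    truth: CrossImpactMatrix,
    disagreement_rate: float,
    max_shift: int = 1,
    n_groups: int = 2,
    seed: int | None = None,
) -> list[GroupScoreSet]:
    """Simulate breakout groups scoring the full matrix with noise.

    Each group reproduces the truth score except that, independently per
    cell with probability *disagreement_rate*, the score is shifted by a
    uniform ±k (1 <= k <= max_shift) and clamped to the scale, so a shift
    that would leave -3..+3 is truncated back (a +3 shifted upward stays
    +3).
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ConfigError(f"disagreement_rate must be in [0, 1], got {disagreement_rate}")
    if max_shift < 1:
        raise ConfigError(f"max_shift must be >= 1, got {max_shift}")
    if n_groups < 1:
        raise ConfigError(f"n_groups must be >= 1, got {n_groups}")
    rng = np.random.default_rng(seed)
    pairs = [(s.source, s.target, s.score) for s in truth.iter_scores()]
    sets = []
    for g in range(n_groups):
        scores = []
        for src, tgt, true_score in pairs:
            score = true_score
            if rng.random() < disagreement_rate:
                k = int(rng.integers(1, max_shift + 1))
                sign = 1 if rng.random() < 0.5 else -1
                score = int(np.clip(true_score + sign * k, -3, 3))
            scores.append(InteractionScore(src, tgt, score))
        sets.append(GroupScoreSet(group_id=f"group-{g + 1}", scores=tuple(scores)))
    return sets


@dataclass(frozen=True)
class IndicatorGenConfig:
    """Linear-trend-plus-noise indicator series generator settings."""

    goal_id: str = "G1"
    indicator: str = "synthetic indicator"
    start_year: int = 2000
    n_years: int = 5
    step: int = 5
    intercept: float = 50.0
    slope: float = 1.0
    noise_sd: float = 0.0
    increase_is_progress: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ConfigError(f"need >= 3 years, got {self.n_years}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.step < 1:
            raise ConfigError(f"step must be >= 1, got {self.step}")


def generate_indicator_series(cfg: IndicatorGenConfig) -> IndicatorSeries:
    """One seeded year->value series: intercept + slope*t + Gaussian noise."""
    rng = np.random.default_rng(cfg.seed)
    years = [cfg.start_year + i * cfg.step for i in range(cfg.n_years)]
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_years) if cfg.noise_sd else np.zeros(cfg.n_years)
    obs = {
        year: float(cfg.intercept + cfg.slope * i * cfg.step + noise[i])
        for i, year in enumerate(years)
    }
    return IndicatorSeries(
        goal_id=cfg.goal_id,
        indicator=cfg.indicator,
        observations=obs,
        increase_is_progress=cfg.increase_is_progress,
    )


# ---------------------------------------------------------------------------
# Cambodia fixtures
# ---------------------------------------------------------------------------

def cambodia_goal_registry() -> GoalRegistry:
    """The 17-goal Cambodia registry (CSDG 1-16 and 18; goal 3 is child
    health, alias "CH")."""
    with resources.as_file(_data_path("cambodia_goals.csv")) as path:
        return GoalRegistry.from_csv(path)


def cambodia_child_health_fixture() -> tuple[dict[str, int], dict[str, int]]:
    """Child health's matrix row and column over the 16 other goals.

    Returns ``(row, column)``: ``row[j]`` is the scored influence of child
    health on goal j; ``column[i]`` the influence of goal i on child health.
    Reconstructed from the published qualitative statements via the
    seven-point scale mapping.
    """
    table = pd.read_csv(_data_path("child_health_links.csv"), dtype={"goal": str})
    row = {
        r.goal: int(r.score) for r in table.itertuples() if r.direction == "out"
    }
    col = {
        r.goal: int(r.score) for r in table.itertuples() if r.direction == "in"
    }
    return row, col


def cambodia_child_health_matrix(
    seed: int | None = None, cfg: MatrixGenConfig | None = None
) -> CrossImpactMatrix:
    """A complete 17-goal matrix embedding the child-health row and column.

    The 16x16 block among the other goals is unavailable in the published
    text; it is filled with zeros when *seed* is None, otherwise drawn from
    the matrix generator. Child health's own influence statistics (row sum,
    column sum, feedback loop) are identical under every completion.
    """
    registry = cambodia_goal_registry()
    row, col = cambodia_child_health_fixture()
    if seed is None:
        w = np.zeros((len(registry), len(registry)), dtype=np.int64)
    else:
        cfg = cfg or MatrixGenConfig(n_goals=len(registry), seed=seed)
        if cfg.seed != seed:
            cfg = replace(cfg, seed=seed)
        w = generate_matrix(cfg, registry=registry).values().copy()
    ch = registry.index(CHILD_HEALTH_ID)
    for gid, score in row.items():
        w[ch, registry.index(gid)] = score
    for gid, score in col.items():
        w[registry.index(gid), ch] = score
    return CrossImpactMatrix(registry, w)


def cambodia_indicator_series() -> list[IndicatorSeries]:
    """The bundled Cambodia key-indicator table as IndicatorSeries objects.

    Off-grid observation years (e.g. a 2003 value in a 2000-2019 five-year
    grid) are stored at their true year.
    """
    table = pd.read_csv(_data_path("cambodia_indicators.csv"), dtype={"goal_id": str})
    series = []
    for (goal_id, indicator), grp in table.groupby(
        ["goal_id", "indicator"], sort=False
    ):
        flags = grp["increase_is_progress"].unique()
        if len(flags) != 1:
            raise ConfigError(
                f"inconsistent direction flag for indicator {indicator!r}"
            )
        series.append(
            IndicatorSeries(
                goal_id=goal_id,
                indicator=indicator,
                observations={
                    int(y): float(v) for y, v in zip(grp["year"], grp["value"])
                },
                increase_is_progress=bool(flags[0]),
            )
        )
    return series


def get_indicator(
    series: Sequence[IndicatorSeries], goal_id: str, match: str | None = None
) -> IndicatorSeries:
    """Pick one series by goal id and an optional substring of its name."""
    hits = [
        s
        for s in series
        if s.goal_id == goal_id and (match is None or match.lower() in s.indicator.lower())
    ]
    if len(hits) != 1:
        raise ConfigError(
            f"expected exactly one series for goal {goal_id!r}"
            + (f" matching {match!r}" if match else "")
            + f", found {len(hits)}"
        )
    return hits[0]
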