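"""Direction-recoded paired-observation correlation of indicator series.

Goal indicators run in different directions: a falling mortality rate and a
rising school-completion rate both mean progress. Before correlating, every
series is re-coded so that *larger always means more progress* (values of
decrease-is-progress indicators are negated). Pearson's r is then computed
over the exact intersection of observation years — paired observations only,
no interpolation, since sparse indicator tables would otherwise have data
invented between observations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientOverlapError

DEFAULT_MIN_OVERLAP = 3


@dataclass(frozen=True)
class IndicatorSeries:
    """A year-indexed indicator for one goal.

    ``increase_is_progress`` records the direction of progress: True when a
    rising value moves toward the goal (e.g. electricity access), False when
    a falling value does (e.g. under-five mortality).
    """

    goal_id: str
    indicator: str
    observations: Mapping[int, float]
    increase_is_progress: bool = True

    def __post_init__(self) -> None:
        obs = dict(sorted(self.observations.items()))
        if len(obs) < 2:
            raise ConfigError(
                f"series {self.indicator!r} needs >= 2 observations, got {len(obs)}"
            )
        for year, value in obs.items():
            if not isinstance(year, (int, np.integer)):
                raise ConfigError(f"year {year!r} is not an integer")
            if not np.isfinite(value):
                raise ConfigError(
                    f"non-finite value {value!r} at year {year} in {self.indicator!r}"
                )
        object.__setattr__(self, "observations", obs)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.observations)

    def values_at(self, years) -> np.ndarray:
        return np.array([self.observations[y] for y in years], dtype=float)


def recode_series(s: IndicatorSeries) -> IndicatorSeries:
    """Orient a series so that higher values mean progress.

    Identity for increase-is-progress series; otherwise values are negated
    and the flag set, so applying the recode twice changes nothing further.
    """
    if s.increase_is_progress:
        return s
    return replace(
        s,
        observations={y: -v for y, v in s.observations.items()},
        increase_is_progress=True,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two progress-oriented series on their shared years.

    ``status`` is 'ok' or 'degenerate' (a constant series leaves r undefined;
    it is reported as such, never coerced to 0).
    """

    pair: tuple[str, str]
    r: float | None
    n_overlap: int
    years: tuple[int, ...]
    status: str = "ok"


def progress_correlation(
    a: IndicatorSeries,
    b: IndicatorSeries,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationResult:
    """Paired-observation Pearson correlation of two indicator series.

    Both series are direction-recoded first (a no-op if already oriented).
    Observations pair by exact year match; fewer than *min_overlap* shared
    years raises :class:`InsufficientOverlapError` naming the pair.
    """
    a = recode_series(a)
    b = recode_series(b)
    shared = tuple(sorted(set(a.years) & set(b.years)))
    if len(shared) < min_overlap:
        raise InsufficientOverlapError(
            f"series pair ({a.indicator!r}, {b.indicator!r}) shares only "
            f"{len(shared)} year(s); need >= {min_overlap}"
        )
    x = a.values_at(shared)
    y = b.values_at(shared)
    pair = (a.indicator, b.indicator)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            pair=pair, r=None, n_overlap=len(shared), years=shared,
            status="degenerate",
        )
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(pair=pair, r=r, n_overlap=len(shared), years=shared)


def correlation_table(
    series: list[IndicatorSeries],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
):
    """All-pairs correlation rows for a list of series.

    Returns a pandas DataFrame with one row per unordered indicator pair and
    a status column ('ok', 'degenerate' or 'insufficient-overlap'); pairs
    with too few shared years are reported, not silently dropped. Goal-level
    composites are deliberately not computed — correlations stay
    per-indicator.
    """
    import pandas as pd

    rows = []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            a, b = series[i], series[j]
            try:
                res = progress_correlation(a, b, min_overlap=min_overlap)
                rows.append(
                    {
                        "goal_a": a.goal_id,
                        "indicator_a": a.indicator,
                        "goal_b": b.goal_id,
                        "indicator_b": b.indicator,
                        "r": res.r,
                        "n_overlap": res.n_overlap,
                        "status": res.status,
                    }
                )
            except InsufficientOverlapError:
                shared = set(a.years) & set(b.years)
                rows.append(
                    {
                        "goal_a": a.goal_id,
                        "indicator_a": a.indicator,
                        "goal_b": b.goal_id,
                        "indicator_b": b.indicator,
                        "r": None,
                        "n_overlap": len(shared),
                        "status": "insufficient-overlap",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "goal_a", "indicator_a", "goal_b", "indicator_b",
            "r", "n_overlap", "status",
        ],
    )
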