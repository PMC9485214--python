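"""Monte-Carlo standard errors and intervals for life-table statistics.

A parametric Poisson bootstrap: replicate death counts are drawn as
D*_x ~ Poisson(D_x) with exposures held fixed, rates and the full life table
are recomputed per replicate, and the replicate distribution of the requested
statistic yields its standard error and percentile 95% interval.  Percentile
(rather than normal-approximation) bounds are used because CV replicates can
be visibly skewed in small strata.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import DataError, DomainError
from .lifetable import DEFAULT_A0, life_table_columns
from .variation import moments_from_columns

__all__ = ["UncertaintyResult", "poisson_bootstrap", "replicate_statistics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimate with bootstrap standard error and 95% interval."""

    point: float
    se: float
    lower: float
    upper: float
    reps: int
    seed: int | None


def _stat_from_columns(
    cols: dict[str, np.ndarray],
    grid: AgeGrid,
    stat: str,
    age: float,
) -> np.ndarray:
    idx = grid.index_of(age)
    if stat == "e":
        return cols["ex"][..., idx]
    _, sd = moments_from_columns(cols, grid, idx)
    if stat == "sd":
        return sd
    if stat == "cv":
        return sd / cols["ex"][..., idx]
    raise DomainError(f"unknown statistic {stat!r}; use 'e', 'sd' or 'cv'")


def replicate_statistics(
    mx: np.ndarray,
    grid: AgeGrid,
    stat: str,
    age: float,
    a0: float = DEFAULT_A0,
) -> np.ndarray:
    """Statistic values for an array of schedules, shape ``(..., K)``."""
    cols = life_table_columns(mx, grid, a0)
    return _stat_from_columns(cols, grid, stat, age)


def poisson_bootstrap(
    deaths: np.ndarray,
    exposure: np.ndarray,
    stat: str = "e",
    age: float = 0.0,
    reps: int = 1000,
    seed: int | None = None,
    grid: AgeGrid = DEFAULT_GRID,
    a0: float = DEFAULT_A0,
    resample: bool = True,
    max_redraw_rounds: int = 100,
) -> UncertaintyResult:
    """Bootstrap SE and percentile 95% interval for e, SD or CV at ``age``.

    Replicates whose open-interval draw is zero cannot close a life table and
    are redrawn (logged), up to ``max_redraw_rounds`` rounds.  With
    ``resample=False`` every replicate reuses the observed counts — a
    degenerate run useful for verifying the zero-variance limit.
    """
    deaths = np.asarray(deaths, dtype=np.int64)
    exposure = np.asarray(exposure, dtype=float)
    if reps < 100:
        raise DomainError("bootstrap needs at least 100 replicates")
    if np.any(exposure <= 0):
        raise DataError("bootstrap requires positive exposure in every interval")
    if deaths[-1] <= 0:
        raise DataError("no observed open-interval deaths; life table cannot close")

    point = float(
        replicate_statistics(deaths / exposure, grid, stat, age, a0)
    )
    rng = np.random.default_rng(seed)
    if resample:
        draws = rng.poisson(deaths, size=(reps, deaths.size))
        bad = draws[:, -1] == 0
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > max_redraw_rounds:
                raise DataError(
                    "open-interval replicate kept drawing zero deaths; "
                    "stratum too sparse to bootstrap"
                )
            logger.debug(
                "redrawing %d replicate(s) with empty open interval", bad.sum()
            )
            draws[bad] = rng.poisson(deaths, size=(int(bad.sum()), deaths.size))
            bad = draws[:, -1] == 0
    else:
        # degenerate run: every replicate is the observed data exactly
        return UncertaintyResult(
            point=point, se=0.0, lower=point, upper=point, reps=reps, seed=seed
        )

    stats = replicate_statistics(draws / exposure, grid, stat, age, a0)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return UncertaintyResult(
        point=point,
        se=float(np.std(stats, ddof=1)),
        lower=float(lo),
        upper=float(hi),
        reps=reps,
        seed=seed,
    )
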