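"""Lifespan variation: SD and coefficient of variation of age at death.

The life-table death distribution is treated as a discrete distribution with
mass d_x/l_y at point age x + a_x (conditional on survival to the starting age
y), the convention of life-table dispersion worksheets.  The SD at age y is
the standard deviation of that distribution around its own mean, and the
coefficient of variation divides by remaining life expectancy e_y (optionally
by the total mean age at death y + e_y).

The open-ended interval is the one place a point mass would visibly bias the
result: under low mortality a large share of the cohort survives to the open
age, and collapsing their deaths onto the single age 85 + a_open discards all
dispersion within the group.  Open-interval lifetimes are therefore given a
within-group spread: remaining life beyond the open age is modelled as a
Gompertz variable whose mean is pinned to the life table's own closure value
a_open = 1/m_open and whose slope is estimated from the growth of the rates
across the oldest closed intervals.  When old-age rates are flat the slope is
zero and the model reduces to the exponential (constant-hazard) tail, making
the treatment exactly consistent with the closure used for e at the open age.
The mean age at death is unchanged; the variance gains
d_open/l_y * (kappa * a_open)^2, where kappa is the tail's coefficient of
variation (1 for the exponential, smaller for rising hazards).  Closed
intervals remain point masses; their within-interval spread is a second-order
effect (see the methods note).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import DomainError

__all__ = ["VariationResult", "sd_at_age", "cv_at_age", "moments_from_columns"]


@dataclass(frozen=True)
class VariationResult:
    """SD and CV of age at death among survivors to exact age ``age``."""

    age: float
    sd: float
    e: float
    cv: float


# ---------------------------------------------------------------------------
# Open-interval tail: CV of a Gompertz remaining-life distribution
# ---------------------------------------------------------------------------
# With time rescaled so the mean is 1, the shape of a Gompertz lifetime
# depends only on x = slope * mean.  kappa(x) is its coefficient of
# variation: kappa(0) = 1 (exponential), decreasing as the hazard rises
# faster.  Tabulated once, interpolated thereafter.

_TAIL_X_MAX = 30.0
_tail_grid: tuple[np.ndarray, np.ndarray] | None = None


def _tail_kappa_table() -> tuple[np.ndarray, np.ndarray]:
    global _tail_grid
    if _tail_grid is None:
        xs = np.linspace(0.0, _TAIL_X_MAX, 301)
        u = np.linspace(0.0, 15.0, 3001)  # mean-1 lifetimes: S(15) negligible
        kappas = np.empty_like(xs)
        for i, x in enumerate(xs):
            lo, hi = 1e-8, 60.0
            for _ in range(60):  # bisect the level theta so the mean is 1
                theta = 0.5 * (lo + hi)
                if x > 0:
                    S = np.exp(-theta / x * np.expm1(x * u))
                else:
                    S = np.exp(-theta * u)
                mean = np.trapezoid(S, u)
                if mean > 1.0:
                    lo = theta
                else:
                    hi = theta
            m2 = 2.0 * np.trapezoid(u * S, u)
            kappas[i] = np.sqrt(max(m2 - 1.0, 0.0))
        _tail_grid = (xs, kappas)
    return _tail_grid


def open_tail_cv(m_open, beta) -> np.ndarray:
    """CV of remaining life in the open group for terminal rate ``m_open``
    and Gompertz slope ``beta`` (per year of age); vectorized."""
    xs, ks = _tail_kappa_table()
    x = np.clip(np.asarray(beta, float) / np.asarray(m_open, float), 0.0, _TAIL_X_MAX)
    return np.interp(x, xs, ks)


def _old_age_slope(mx: np.ndarray, grid: AgeGrid) -> np.ndarray:
    """Gompertz slope estimated from the last two closed intervals' rates
    (log growth per year of age between their midpoints); 0 when either rate
    is unusable or mortality is not rising."""
    m_hi = mx[..., -2]
    m_lo = mx[..., -3]
    gap = 0.5 * (grid.widths[-2] + grid.widths[-3])
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(m_hi / m_lo) / gap
    return np.where((m_hi > 0) & (m_lo > 0) & np.isfinite(beta), np.maximum(beta, 0.0), 0.0)


def moments_from_columns(
    cols: dict[str, np.ndarray],
    grid: AgeGrid,
    y_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(mean age at death, SD of age at death) conditional on reaching the
    interval ``y_index``, vectorized over leading axes of the columns."""
    starts = grid.start_array
    ages = starts + cols["ax"]  # point age assigned to deaths in each interval
    w = cols["dx"][..., y_index:]
    ly = cols["lx"][..., y_index]
    if np.any(ly <= 0):
        raise DomainError("no survivors at the requested starting age")
    mu = np.sum(w * ages[..., y_index:], axis=-1) / ly
    var = np.sum(w * (ages[..., y_index:] - mu[..., None]) ** 2, axis=-1) / ly
    # within-open-group spread: Gompertz tail with mean a_open = 1/m
    kappa = open_tail_cv(cols["mx"][..., -1], _old_age_slope(cols["mx"], grid))
    var = var + w[..., -1] * (kappa * cols["ax"][..., -1]) ** 2 / ly
    return mu, np.sqrt(np.maximum(var, 0.0))


def _columns_from_table(table: pd.DataFrame) -> dict[str, np.ndarray]:
    return {k: table[k].to_numpy(dtype=float) for k in ("mx", "ax", "lx", "dx", "ex")}


def _grid_from_table(table: pd.DataFrame) -> AgeGrid:
    return AgeGrid(starts=tuple(float(a) for a in table["age_start"]))


def sd_at_age(table: pd.DataFrame, y: float = 0.0) -> float:
    """Standard deviation of age at death among survivors to grid age ``y``.

    Centering uses the d_x-weighted mean age at death itself (equal to
    y + e_y under the table's accounting identity), so the variance is
    non-negative even for a table whose columns are not mutually consistent.
    """
    grid = _grid_from_table(table)
    idx = grid.index_of(y)
    _, sd = moments_from_columns(_columns_from_table(table), grid, idx)
    return float(sd)


def cv_at_age(
    table: pd.DataFrame,
    y: float = 0.0,
    normalize: str = "remaining",
) -> VariationResult:
    """Coefficient of variation of age at death at grid age ``y``.

    ``normalize="remaining"`` (default) divides the SD by the remaining life
    expectancy e_y; ``normalize="total"`` divides by the total mean age at
    death y + e_y.  The two coincide at birth.
    """
    if normalize not in ("remaining", "total"):
        raise DomainError(f"unknown CV normalization {normalize!r}")
    grid = _grid_from_table(table)
    idx = grid.index_of(y)
    cols = _columns_from_table(table)
    _, sd = moments_from_columns(cols, grid, idx)
    ey = float(cols["ex"][idx])
    denom = ey if normalize == "remaining" else float(y) + ey
    if denom <= 0:
        raise DomainError("life expectancy must be positive to form a CV")
    return VariationResult(age=float(y), sd=float(sd), e=ey, cv=float(sd) / denom)
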