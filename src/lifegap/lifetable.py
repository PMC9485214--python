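"""Abridged period life tables.

Central death rates m_x are converted to interval death probabilities with the
Greville/Chiang relation q_x = n*m_x / (1 + (n - a_x)*m_x), the survivorship
column is run from a radix of 100,000, and person-years follow the standard
accounting L_x = n*l_{x+n} + a_x*d_x.  The open-ended interval is closed with a
constant-hazard assumption, so e at the open age equals 1/m there.

Under this accounting the death distribution placed at point ages x + a_x
reproduces e_0 exactly (sum of d_x*(x+a_x)/l_0 == e_0), which is what anchors
the lifespan-variation computations in :mod:`lifegap.variation`.

All column functions accept arrays of schedules (shape ``(..., K)``) so that
bootstrap replicates can be processed in one vectorized pass.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import ClosureError, DomainError

__all__ = [
    "RADIX",
    "default_ax",
    "mx_to_qx",
    "life_table_columns",
    "build_life_table",
    "life_expectancy_at",
]

RADIX = 100_000.0

#: Average years lived in [0,1) by infants who die there.  A conventional
#: low-mortality choice; override through the ``a0`` arguments.
DEFAULT_A0 = 0.1

#: Average years lived in [1,5) by children who die there.
DEFAULT_A_CHILD = 1.5


def default_ax(
    mx: np.ndarray,
    grid: AgeGrid = DEFAULT_GRID,
    a0: float = DEFAULT_A0,
) -> np.ndarray:
    """Separation factors a_x for every interval of ``grid``.

    Rules: a = ``a0`` for the infant interval [0,1); 1.5 for the child
    interval [1,5); n/2 for other closed intervals; 1/m for the open interval
    (constant-hazard closure).

    Parameters
    ----------
    mx
        Central death rates, shape ``(..., K)``; only the terminal rate is
        used (for the open-interval closure).
    """
    mx = np.asarray(mx, dtype=float)
    K = grid.n_intervals
    if mx.shape[-1] != K:
        raise DomainError(f"schedule has {mx.shape[-1]} rates, grid has {K} intervals")
    m_open = mx[..., -1]
    if np.any(m_open <= 0):
        raise ClosureError(
            "open-interval rate must be positive to close the life table"
        )
    starts = grid.start_array
    widths = grid.widths
    ax_closed = widths / 2.0
    if starts[0] == 0.0 and widths[0] == 1.0:
        ax_closed[0] = a0
    if K > 1 and starts[1] == 1.0 and widths[1] == 4.0:
        ax_closed[1] = DEFAULT_A_CHILD
    ax = np.broadcast_to(ax_closed, mx.shape).copy()
    ax[..., -1] = 1.0 / m_open
    return ax


def mx_to_qx(mx: np.ndarray, n: np.ndarray, ax: np.ndarray) -> np.ndarray:
    """Greville/Chiang conversion of central rates to death probabilities.

    q = n*m / (1 + (n-a)*m), clipped to at most 1.  Where ``n`` is infinite
    (open interval) q is 1.
    """
    mx = np.asarray(mx, dtype=float)
    n = np.asarray(n, dtype=float)
    ax = np.asarray(ax, dtype=float)
    if np.any(mx < 0) or np.any(np.isnan(mx)):
        raise DomainError("central death rates must be finite and non-negative")
    with np.errstate(invalid="ignore"):
        q = n * mx / (1.0 + (n - ax) * mx)
    q = np.where(np.isinf(n) | np.isnan(q), 1.0, q)
    return np.minimum(q, 1.0)


def life_table_columns(
    mx: np.ndarray,
    grid: AgeGrid = DEFAULT_GRID,
    a0: float = DEFAULT_A0,
    radix: float = RADIX,
    ax: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """All life-table columns for one or many schedules.

    ``mx`` has shape ``(..., K)``; every returned column has the same shape.
    ``ax`` overrides the default separation factors (the open entry is still
    forced to 1/m for closure).  This is the vectorized work-horse behind
    :func:`build_life_table` and the Poisson bootstrap.
    """
    mx = np.asarray(mx, dtype=float)
    if ax is None:
        ax = default_ax(mx, grid, a0)
    else:
        ax = np.broadcast_to(np.asarray(ax, dtype=float), mx.shape).copy()
        if np.any(mx[..., -1] <= 0):
            raise ClosureError(
                "open-interval rate must be positive to close the life table"
            )
        ax[..., -1] = 1.0 / mx[..., -1]
    n = np.broadcast_to(grid.widths, mx.shape)
    qx = mx_to_qx(mx, n, ax)

    surv = np.cumprod(1.0 - qx[..., :-1], axis=-1)
    lx = np.concatenate(
        [np.full(mx.shape[:-1] + (1,), radix), radix * surv], axis=-1
    )
    dx = lx * qx  # open interval: q=1 so everyone remaining dies there

    l_next = np.concatenate([lx[..., 1:], np.zeros(mx.shape[:-1] + (1,))], axis=-1)
    Lx = np.where(np.isinf(n), 0.0, n) * l_next + ax * dx  # open: L = l/m = a*d
    Tx = np.flip(np.cumsum(np.flip(Lx, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return {"mx": mx, "ax": ax, "qx": qx, "lx": lx, "dx": dx,
            "Lx": Lx, "Tx": Tx, "ex": ex}


def build_life_table(
    schedule: np.ndarray,
    grid: AgeGrid = DEFAULT_GRID,
    a0: float = DEFAULT_A0,
    radix: float = RADIX,
    ax: np.ndarray | None = None,
) -> pd.DataFrame:
    """Abridged life table for a single mortality schedule.

    Returns a DataFrame with one row per age interval and columns
    ``age_start, n, mx, ax, qx, lx, dx, Lx, Tx, ex`` (the emission schema).
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 1:
        raise DomainError("build_life_table expects a single 1-d schedule")
    cols = life_table_columns(schedule, grid, a0, radix, ax)
    out = pd.DataFrame({"age_start": grid.start_array, "n": grid.widths})
    for name in ("mx", "ax", "qx", "lx", "dx", "Lx", "Tx", "ex"):
        out[name] = cols[name]
    return out


def life_expectancy_at(table: pd.DataFrame, age: float) -> float:
    """Remaining life expectancy e_x at a grid start age (no interpolation)."""
    hit = table.index[table["age_start"] == float(age)]
    if len(hit) == 0:
        raise DomainError(
            f"age {age} is not an interval start of this table; "
            f"valid starts are {list(table['age_start'])}"
        )
    return float(table.loc[hit[0], "ex"])
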