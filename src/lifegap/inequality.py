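"""Between-group inequality measures and trend statistics.

Absolute inequality is the metropolitan value minus the nonmetropolitan value
of the same measure for the same race-gender group; relative inequality is
their ratio.  The range gap within a gender-urbanicity-period cell is the
spread between the best-off and worst-off race groups.  Trend change compares
a gap between an earlier and a later period ("narrowed by" when positive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError
from .synthetic import RACE_LEVELS

__all__ = [
    "InequalityRecord",
    "absolute_gap",
    "relative_ratio",
    "range_gap",
    "trend_change",
    "describe_trend_change",
    "measure_correlation",
    "inequality_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InequalityRecord:
    """One absolute difference and ratio between two strata for one measure."""

    measure: str
    group_a: str
    group_b: str
    absolute: float
    ratio: float
    period: str


def absolute_gap(value_a: float, value_b: float) -> float:
    """a - b, in the units of the measure (group a is the metropolitan or
    better-off member by convention)."""
    return float(value_a) - float(value_b)


def relative_ratio(value_a: float, value_b: float) -> float:
    """a / b; the denominator must be positive."""
    if value_b <= 0:
        raise DomainError("ratio denominator must be positive")
    return float(value_a) / float(value_b)


def range_gap(values: dict[str, float]) -> tuple[str, str, float]:
    """(best group, worst group, max - min) across race groups in one cell.

    Ties are broken by the fixed race-label order (H, NHW, NHB, NHAPI) and
    flagged to the log.
    """
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    if len(finite) < 2:
        raise DomainError("range gap needs at least two finite values")
    order = {r: i for i, r in enumerate(RACE_LEVELS)}
    keys = sorted(finite, key=lambda k: order.get(k, len(order)))
    vmax = max(finite.values())
    vmin = min(finite.values())
    top = next(k for k in keys if finite[k] == vmax)
    bottom = next(k for k in keys if finite[k] == vmin)
    if sum(v == vmax for v in finite.values()) > 1 or sum(
        v == vmin for v in finite.values()
    ) > 1:
        logger.info("range_gap tie broken by fixed race order in %s", finite)
    return top, bottom, vmax - vmin


def trend_change(gap_t1: float, gap_t2: float) -> float:
    """gap(earlier) - gap(later): positive = the gap narrowed."""
    return float(gap_t1) - float(gap_t2)


def describe_trend_change(gap_t1: float, gap_t2: float) -> str:
    change = trend_change(gap_t1, gap_t2)
    if change > 0:
        return f"narrowed by {change:g}"
    if change < 0:
        return f"widened by {-change:g}"
    return "unchanged"


def measure_correlation(x, y) -> float:
    """Pearson correlation between two measures paired across strata."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("correlation needs at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for a constant measure")
    return float(sps.pearsonr(x, y).statistic)


def inequality_report(results: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Metro-nonmetro and between-race inequalities from a results table.

    ``results`` has one row per stratum-period with key columns
    ``race_ethnicity, gender, urbanicity, period`` and one column per measure
    (e.g. ``e0, sd0, cv0``); urbanicity must be 2-level.  Emits one row per
    comparison: metropolitan-vs-nonmetropolitan per race-gender ("absolute",
    "ratio", "direction"), plus between-race range gaps per
    gender-urbanicity (race column set to "range", group names in
    ``urbanicity_a``/``urbanicity_b``).
    """
    rows: list[dict] = []
    for measure in measures:
        if measure not in results.columns:
            raise DomainError(f"measure {measure!r} missing from results")
        pivot = results.pivot_table(
            index=["race_ethnicity", "gender", "period"],
            columns="urbanicity",
            values=measure,
        )
        for (race, gender, period), row in pivot.iterrows():
            if {"metropolitan", "nonmetropolitan"} <= set(row.dropna().index):
                a, b = row["metropolitan"], row["nonmetropolitan"]
                diff = absolute_gap(a, b)
                rows.append(
                    {
                        "measure": measure,
                        "period": period,
                        "gender": gender,
                        "race_ethnicity": race,
                        "urbanicity_a": "metropolitan",
                        "urbanicity_b": "nonmetropolitan",
                        "absolute": diff,
                        "ratio": relative_ratio(a, b),
                        "direction": "metro_higher" if diff > 0 else (
                            "metro_lower" if diff < 0 else "equal"
                        ),
                    }
                )
        by_cell = results[results["race_ethnicity"].isin(RACE_LEVELS)].groupby(
            ["gender", "urbanicity", "period"]
        )
        for (gender, urb, period), part in by_cell:
            values = dict(zip(part["race_ethnicity"], part[measure]))
            if len(values) < 2:
                continue
            top, bottom, spread = range_gap(values)
            rows.append(
                {
                    "measure": measure,
                    "period": period,
                    "gender": gender,
                    "race_ethnicity": "range",
                    "urbanicity_a": f"{urb}:{top}",
                    "urbanicity_b": f"{urb}:{bottom}",
                    "absolute": spread,
                    "ratio": relative_ratio(values[top], values[bottom]),
                    "direction": "range",
                }
            )
    return pd.DataFrame(rows)
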