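"""Reading, cleaning and pooling of stratified vital-registration counts.

The cleaning chain mirrors standard NCHS-style practice: merge counties whose
boundaries changed during the study window, drop Hispanic counts for the
state-years NCHS flags as unreliable, attach county urbanicity codes (6-level,
optionally collapsed to metropolitan/nonmetropolitan), pool calendar years
into 5-year periods, and form central death rates per stratum.

Every step conserves total deaths and person-years, except the exclusion
step, whose removed totals are reported to the module logger.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import ConfigError, DataError, IntegrityError, MappingError, ParseError
from .synthetic import (
    DEFAULT_PERIODS,
    GENDER_LEVELS,
    RACE_LEVELS,
    URBANICITY6_LEVELS,
)

__all__ = [
    "COUNT_COLUMNS",
    "METRO_COLLAPSE",
    "read_counts",
    "read_crosswalk",
    "read_merges",
    "read_exclusions",
    "apply_county_merges",
    "apply_exclusions",
    "map_urbanicity",
    "pool_and_aggregate",
    "compute_rates",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = (
    "year",
    "county_fips",
    "age_group",
    "gender",
    "race_ethnicity",
    "deaths",
    "population",
)

#: 6-level NCHS-style codes -> 2-level metropolitan split.
METRO_COLLAPSE = {
    "large_central": "metropolitan",
    "large_fringe": "metropolitan",
    "medium": "metropolitan",
    "small": "metropolitan",
    "micropolitan": "nonmetropolitan",
    "noncore": "nonmetropolitan",
}

_CELL_KEY = ["year", "county_fips", "age_group", "gender", "race_ethnicity"]


def _line_numbers(mask: pd.Series) -> str:
    """CSV line numbers (header = line 1) for the first few offending rows."""
    lines = (mask[mask].index[:5] + 2).tolist()
    return ", ".join(str(i) for i in lines)


def read_counts(
    path: str | Path,
    grid: AgeGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Read and validate a stratified counts CSV.

    Enforces the fixed label vocabularies, non-negative integer counts, and
    uniqueness of (year, county, age, gender, race) cells.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"county_fips": str, "age_group": str})
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    table = table[list(COUNT_COLUMNS)].copy()

    checks = {
        "age_group": ~table["age_group"].isin(grid.labels),
        "gender": ~table["gender"].isin(GENDER_LEVELS),
        "race_ethnicity": ~table["race_ethnicity"].isin(RACE_LEVELS),
    }
    for col, bad in checks.items():
        if bad.any():
            raise ParseError(
                f"{path}: unknown {col} label "
                f"{table.loc[bad, col].iloc[0]!r} at line(s) {_line_numbers(bad)}"
            )
    for col in ("year", "deaths", "population"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.any():
            raise ParseError(
                f"{path}: non-integer or negative {col} "
                f"at line(s) {_line_numbers(bad)}"
            )
        table[col] = numeric.astype(np.int64)
    bad_fips = table["county_fips"].isna() | (table["county_fips"].str.len() != 5)
    if bad_fips.any():
        raise ParseError(
            f"{path}: county_fips must be 5-character strings, "
            f"bad at line(s) {_line_numbers(bad_fips)}"
        )

    dup = table.duplicated(subset=_CELL_KEY)
    if dup.any():
        raise IntegrityError(
            f"{path}: duplicated cell(s) at line(s) {_line_numbers(dup)}"
        )
    return table


def read_crosswalk(path: str | Path) -> pd.DataFrame:
    """county_fips -> urbanicity6 crosswalk."""
    table = pd.read_csv(path, dtype={"county_fips": str})
    for col in ("county_fips", "urbanicity6"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = ~table["urbanicity6"].isin(URBANICITY6_LEVELS)
    if bad.any():
        raise ParseError(
            f"{path}: unknown urbanicity6 code "
            f"{table.loc[bad, 'urbanicity6'].iloc[0]!r}"
        )
    if table["county_fips"].duplicated().any():
        raise IntegrityError(f"{path}: duplicated county_fips in crosswalk")
    return table[["county_fips", "urbanicity6"]]


def read_merges(path: str | Path) -> pd.DataFrame:
    """County-merge map: old_fips -> new_fips."""
    table = pd.read_csv(path, dtype={"old_fips": str, "new_fips": str})
    for col in ("old_fips", "new_fips"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return table[["old_fips", "new_fips"]]


def read_exclusions(path: str | Path) -> pd.DataFrame:
    """Exclusion list: state_prefix, year_start, year_end, race_ethnicity."""
    table = pd.read_csv(path, dtype={"state_prefix": str})
    needed = ("state_prefix", "year_start", "year_end", "race_ethnicity")
    for col in needed:
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return table[list(needed)]


def apply_county_merges(table: pd.DataFrame, merges: pd.DataFrame) -> pd.DataFrame:
    """Fold counts of merged counties into their targets.

    Cell-wise sums land under the target fips; total deaths and person-years
    are unchanged.
    """
    if len(merges) == 0:
        return table.copy()
    mapping = dict(zip(merges["old_fips"], merges["new_fips"]))
    out = table.copy()
    out["county_fips"] = out["county_fips"].map(lambda f: mapping.get(f, f))
    out = (
        out.groupby(_CELL_KEY, as_index=False, sort=False)[["deaths", "population"]]
        .sum()
    )
    return out


def apply_exclusions(table: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop counts matching (state prefix, year range, race) exclusion rules.

    The state is the first two characters of the county fips.  Removed death
    and person-year totals, and the removed fraction of the affected race's
    person-years, are reported to the log; an empty match is legal.
    """
    if len(exclusions) == 0:
        return table.copy()
    drop = pd.Series(False, index=table.index)
    state = table["county_fips"].str[:2]
    for rule in exclusions.itertuples(index=False):
        drop |= (
            (state == rule.state_prefix)
            & (table["year"] >= int(rule.year_start))
            & (table["year"] <= int(rule.year_end))
            & (table["race_ethnicity"] == rule.race_ethnicity)
        )
    removed = table[drop]
    for race, part in removed.groupby("race_ethnicity"):
        total_py = table.loc[table["race_ethnicity"] == race, "population"].sum()
        frac = part["population"].sum() / total_py if total_py else 0.0
        logger.info(
            "exclusions removed %d deaths / %d person-years (%.3f%% of %s "
            "person-years)",
            part["deaths"].sum(), part["population"].sum(), 100 * frac, race,
        )
    return table[~drop].copy()


def excluded_fraction(table: pd.DataFrame, exclusions: pd.DataFrame,
                      race: str = "H") -> float:
    """Fraction of a race's person-years that the exclusion rules remove."""
    kept = apply_exclusions(table, exclusions)
    total = table.loc[table["race_ethnicity"] == race, "population"].sum()
    if total == 0:
        return 0.0
    kept_py = kept.loc[kept["race_ethnicity"] == race, "population"].sum()
    return float((total - kept_py) / total)


def map_urbanicity(
    table: pd.DataFrame,
    crosswalk: pd.DataFrame,
    levels: int = 2,
) -> pd.DataFrame:
    """Attach an ``urbanicity`` column from the county crosswalk.

    ``levels=6`` passes the codes through; ``levels=2`` collapses them to
    metropolitan/nonmetropolitan.
    """
    if levels not in (2, 6):
        raise ConfigError("urbanicity levels must be 2 or 6")
    lookup = dict(zip(crosswalk["county_fips"], crosswalk["urbanicity6"]))
    unmapped = sorted(set(table["county_fips"]) - set(lookup))
    if unmapped:
        raise MappingError(
            f"counties missing from the urbanicity crosswalk: "
            f"{', '.join(unmapped[:10])}"
        )
    out = table.copy()
    urb6 = out["county_fips"].map(lookup)
    out["urbanicity"] = urb6 if levels == 6 else urb6.map(METRO_COLLAPSE)
    return out


def _period_lookup(periods) -> dict[int, str]:
    lookup: dict[int, str] = {}
    for label, y0, y1 in periods:
        for y in range(int(y0), int(y1) + 1):
            if y in lookup:
                raise ConfigError(f"year {y} belongs to more than one period")
            lookup[y] = label
    return lookup


def pool_and_aggregate(
    table: pd.DataFrame,
    periods=DEFAULT_PERIODS,
    grid: AgeGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Pool years into periods and sum counts over counties within urbanicity.

    Requires an ``urbanicity`` column (see :func:`map_urbanicity`).  Returns
    one row per (race, gender, urbanicity, period, age_group) with summed
    ``deaths`` and ``person_years``; age groups are ordered along the grid.
    Years outside every period raise a configuration error.
    """
    if "urbanicity" not in table.columns:
        raise ConfigError("pool_and_aggregate needs an urbanicity column")
    lookup = _period_lookup(periods)
    stray = sorted(set(table["year"]) - set(lookup))
    if stray:
        raise ConfigError(f"years outside all periods: {stray}")
    out = table.copy()
    out["period"] = out["year"].map(lookup)
    out = out.rename(columns={"population": "person_years"})
    pooled = (
        out.groupby(
            ["race_ethnicity", "gender", "urbanicity", "period", "age_group"],
            as_index=False,
            sort=False,
        )[["deaths", "person_years"]]
        .sum()
    )
    order = {lab: i for i, lab in enumerate(grid.labels)}
    pooled["_age_order"] = pooled["age_group"].map(order)
    pooled = (
        pooled.sort_values(
            ["race_ethnicity", "gender", "urbanicity", "period", "_age_order"]
        )
        .drop(columns="_age_order")
        .reset_index(drop=True)
    )
    return pooled


def compute_rates(
    pooled: pd.DataFrame,
    grid: AgeGrid = DEFAULT_GRID,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Central death rates m_x = D_x / N_x per stratum.

    Returns the rate table plus the list of stratum keys that were dropped as
    unusable: any interval with deaths but no exposure is a data error, while
    a stratum with an empty interval (or no open-interval deaths, which
    prevents life-table closure) is excluded with a logged warning.
    """
    key_cols = ["race_ethnicity", "gender", "urbanicity", "period"]
    dropped: list[tuple] = []
    frames: list[pd.DataFrame] = []
    open_label = grid.labels[-1]
    for key, part in pooled.groupby(key_cols, sort=False):
        if len(part) != grid.n_intervals or set(part["age_group"]) != set(grid.labels):
            raise DataError(f"stratum {key}: incomplete age coverage")
        zero_n = part["person_years"] == 0
        if (zero_n & (part["deaths"] > 0)).any():
            raise DataError(f"stratum {key}: deaths recorded with zero exposure")
        open_deaths = part.loc[part["age_group"] == open_label, "deaths"].iloc[0]
        if zero_n.any() or open_deaths == 0:
            logger.warning(
                "stratum %s unusable (zero exposure interval or no "
                "open-interval deaths); excluded", (key,)
            )
            dropped.append(key)
            continue
        part = part.copy()
        part["mx"] = part["deaths"] / part["person_years"]
        frames.append(part)
    if not frames:
        return pooled.iloc[0:0].assign(mx=np.nan), dropped
    return pd.concat(frames, ignore_index=True), dropped
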