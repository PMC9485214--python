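"""Synthetic vital-registration data with known ground-truth mortality.

The generating hazard is a Siler schedule — an exponentially decaying infant
component, a constant background, and a Gompertz senescent component:

    h(t) = a1*exp(-b1*t) + c + a2*exp(b2*t)

which reproduces the infant-mortality hump and old-age acceleration that the
abridged age grid is designed around.  Group structure (race/ethnicity,
gender, urbanicity) is proportional on the hazard, with a secular improvement
factor applied multiplicatively per calendar year.  Death counts are Poisson
draws around expected deaths m_x * N_x, so every downstream stage of the
pipeline can be tested against exact expectations.

Ground truth: the truth table reports e0, sd0 and cv0 of the *abridged-grid*
life table built from the exact expected pooled rates — i.e. the estimand the
pipeline targets, uncontaminated by sampling noise.  The moments of the
continuous hazard itself are available through :func:`continuous_moments`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import ConfigError, DomainError
from .lifetable import life_table_columns
from .variation import moments_from_columns

__all__ = [
    "SilerParams",
    "ScenarioConfig",
    "StudyBundle",
    "siler_hazard",
    "cumulative_hazard",
    "survival",
    "continuous_moments",
    "schedule_from_siler",
    "sample_lifetimes",
    "simulate_counts",
    "random_siler_params",
    "make_study_dataset",
    "RACE_LEVELS",
    "GENDER_LEVELS",
    "URBANICITY6_LEVELS",
]

logger = logging.getLogger(__name__)

RACE_LEVELS = ("H", "NHW", "NHB", "NHAPI")
GENDER_LEVELS = ("man", "woman")
URBANICITY6_LEVELS = (
    "large_central",
    "large_fringe",
    "medium",
    "small",
    "micropolitan",
    "noncore",
)

_SURVIVAL_FLOOR = 1e-10  # integration cutoff: survival below this is ignored


@dataclass(frozen=True)
class SilerParams:
    """Parameters of the Siler hazard, all in 1/year.

    ``a1``/``b1`` scale and decay rate of the infant component, ``c`` the
    age-constant background, ``a2``/``b2`` scale and growth rate of the
    senescent (Gompertz) component.
    """

    a1: float
    b1: float
    c: float
    a2: float
    b2: float

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "c", "a2", "b2"):
            if getattr(self, name) < 0:
                raise DomainError(f"Siler parameter {name} must be >= 0")
        # a schedule with no background and no senescent component is legal
        # to evaluate but improper (survival does not reach 0); integration
        # operations will reject it when they cannot reach the survival floor

    def scaled(self, k: float) -> "SilerParams":
        """Proportional-hazards scaling: multiply every scale parameter by k."""
        if k <= 0:
            raise DomainError("hazard multiplier must be positive")
        return replace(self, a1=self.a1 * k, c=self.c * k, a2=self.a2 * k)


def siler_hazard(params: SilerParams, age) -> np.ndarray | float:
    """Hazard h(age) = a1*exp(-b1*age) + c + a2*exp(b2*age)."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise DomainError("age must be non-negative")
    h = (
        params.a1 * np.exp(-params.b1 * age_arr)
        + params.c
        + params.a2 * np.exp(params.b2 * age_arr)
    )
    return h if age_arr.ndim else float(h)


def cumulative_hazard(params: SilerParams, t) -> np.ndarray | float:
    """Closed-form integrated hazard H(t) = int_0^t h(u) du."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be non-negative")
    if params.a1 > 0 and params.b1 > 0:
        infant = params.a1 / params.b1 * (1.0 - np.exp(-params.b1 * t_arr))
    else:
        infant = params.a1 * t_arr
    if params.a2 > 0 and params.b2 > 0:
        old = params.a2 / params.b2 * np.expm1(params.b2 * t_arr)
    else:
        old = params.a2 * t_arr
    H = infant + params.c * t_arr + old
    return H if t_arr.ndim else float(H)


def survival(params: SilerParams, t) -> np.ndarray | float:
    """S(t) = exp(-H(t))."""
    return np.exp(-np.asarray(cumulative_hazard(params, t)))


def _integration_cutoff(params: SilerParams) -> float:
    """Smallest convenient age beyond which survival is below the floor."""
    target = -np.log(_SURVIVAL_FLOOR)
    t = 128.0
    while cumulative_hazard(params, t) < target:
        t *= 2.0
        if t > 65536.0:  # pathological near-zero hazard
            raise DomainError("hazard too small to reach the survival floor")
    return t


def _fine_grid(params: SilerParams, step: float) -> tuple[np.ndarray, np.ndarray]:
    """(ages, survival) on a uniform grid out to the survival floor."""
    if step <= 0:
        raise ConfigError("integration step must be positive")
    cutoff = _integration_cutoff(params)
    t = np.arange(0.0, cutoff + step, step)
    return t, np.exp(-np.asarray(cumulative_hazard(params, t)))


def continuous_moments(
    params: SilerParams, y: float = 0.0, step: float = 0.01
) -> tuple[float, float]:
    """Exact (e_y, sd_y) of the continuous hazard by fine-grid quadrature.

    Remaining life expectancy and SD of age at death among survivors to exact
    age ``y``; both in years.
    """
    t, S = _fine_grid(params, step)
    keep = t >= y
    t, S = t[keep], S[keep]
    Sy = float(np.exp(-cumulative_hazard(params, y)))
    e = float(np.trapezoid(S, t)) / Sy
    m2 = 2.0 * float(np.trapezoid((t - y) * S, t)) / Sy  # E[(T-y)^2 | T>y]
    var = m2 - e * e
    return e, float(np.sqrt(max(var, 0.0)))


def schedule_from_siler(
    params: SilerParams,
    grid: AgeGrid = DEFAULT_GRID,
    step: float = 0.01,
) -> np.ndarray:
    """Per-interval central death rates m_x implied by the hazard.

    m_x is the stationary-population rate: deaths over person-years within the
    interval, i.e. int h*S over the interval divided by int S, evaluated on a
    fine uniform grid (the open interval integrates to the survival floor).
    """
    t, S = _fine_grid(params, step)
    hS = np.asarray(siler_hazard(params, t)) * S
    edges = list(grid.start_array) + [t[-1]]
    mx = np.empty(grid.n_intervals)
    for i in range(grid.n_intervals):
        lo, hi = edges[i], edges[i + 1]
        sel = (t >= lo) & (t <= hi)
        deaths = np.trapezoid(hS[sel], t[sel])
        py = np.trapezoid(S[sel], t[sel])
        mx[i] = deaths / py
    return mx


def sample_lifetimes(
    params: SilerParams,
    n: int,
    rng: np.random.Generator,
    step: float = 0.01,
) -> np.ndarray:
    """Draw ``n`` exact ages at death by inverting the cumulative hazard."""
    t, _ = _fine_grid(params, step)
    H = np.asarray(cumulative_hazard(params, t))
    e = rng.exponential(size=n)
    return np.interp(e, H, t)  # beyond the floor: clamped at the cutoff


def simulate_counts(
    schedule: np.ndarray,
    exposures: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Poisson death counts with mean m_x * N_x, reproducible under a seed."""
    schedule = np.asarray(schedule, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if np.any(exposures < 0):
        raise DomainError("exposures must be non-negative")
    if np.any(schedule < 0):
        raise DomainError("rates must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.poisson(schedule * exposures)


def random_siler_params(
    rng: np.random.Generator,
    e0_range: tuple[float, float] = (45.0, 90.0),
    max_tries: int = 1000,
) -> SilerParams:
    """Draw a plausible human Siler schedule, rejection-sampled so that the
    continuous-hazard life expectancy falls inside ``e0_range``."""
    for _ in range(max_tries):
        params = SilerParams(
            a1=float(np.exp(rng.uniform(np.log(2e-3), np.log(3e-2)))),
            b1=float(rng.uniform(0.8, 3.0)),
            c=float(np.exp(rng.uniform(np.log(5e-5), np.log(1.5e-3)))),
            a2=float(np.exp(rng.uniform(np.log(5e-6), np.log(1e-4)))),
            b2=float(rng.uniform(0.08, 0.115)),
        )
        e0, _ = continuous_moments(params, step=0.05)
        if e0_range[0] <= e0 <= e0_range[1]:
            return params
    raise DomainError("could not draw a schedule inside the e0 range")


# ---------------------------------------------------------------------------
# Study-scale scenario
# ---------------------------------------------------------------------------

#: Baseline hazard anchored to circa-1990 US low-risk mortality (women in
#: large central metros): e0 near 79, infant death probability near 0.8%.
#: The annual improvement factor carries later calendar years below this.
DEFAULT_BASELINE = SilerParams(a1=0.02, b1=2.5, c=0.0003, a2=1.2e-5, b2=0.106)

DEFAULT_PERIODS: tuple[tuple[str, int, int], ...] = (
    ("1990-1994", 1990, 1994),
    ("1995-1999", 1995, 1999),
    ("2000-2004", 2000, 2004),
    ("2005-2009", 2005, 2009),
    ("2010-2014", 2010, 2014),
    ("2015-2019", 2015, 2019),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Conditions of a synthetic vital-registration study.

    Hazard multipliers are proportional on the whole Siler hazard; the annual
    improvement factor multiplies the hazard once per year elapsed since the
    first study year.  Default differentials emulate the familiar US
    orderings: an Asian/Pacific Islander advantage, a Hispanic advantage over
    non-Hispanic White, a Black disadvantage, a male disadvantage of roughly
    five years of e0, and a rural penalty growing across the six urbanicity
    levels.
    """

    baseline: SilerParams = DEFAULT_BASELINE
    race_multipliers: dict[str, float] = field(
        default_factory=lambda: {"H": 0.82, "NHW": 1.0, "NHB": 1.45, "NHAPI": 0.55}
    )
    gender_multipliers: dict[str, float] = field(
        default_factory=lambda: {"man": 1.45, "woman": 1.0}
    )
    urbanicity_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "large_central": 1.00,
            "large_fringe": 0.95,
            "medium": 1.03,
            "small": 1.06,
            "micropolitan": 1.12,
            "noncore": 1.16,
        }
    )
    race_shares: dict[str, float] = field(
        default_factory=lambda: {"H": 0.18, "NHW": 0.61, "NHB": 0.13, "NHAPI": 0.08}
    )
    annual_improvement: float = 0.99
    years: tuple[int, int] = (1990, 2019)
    counties_per_level: int = 3
    county_pop_scale: float = 100_000.0
    county_pop_sigma: float = 0.5
    county_fips: dict[str, tuple[str, ...]] | None = None
    seed: int = 20190101

    def __post_init__(self) -> None:
        for name, table in (
            ("race_multipliers", self.race_multipliers),
            ("gender_multipliers", self.gender_multipliers),
            ("urbanicity_multipliers", self.urbanicity_multipliers),
        ):
            if any(v <= 0 for v in table.values()):
                raise ConfigError(f"{name} must all be positive")
        if set(self.race_multipliers) != set(RACE_LEVELS):
            raise ConfigError(f"race_multipliers must cover {RACE_LEVELS}")
        if set(self.gender_multipliers) != set(GENDER_LEVELS):
            raise ConfigError(f"gender_multipliers must cover {GENDER_LEVELS}")
        if set(self.urbanicity_multipliers) != set(URBANICITY6_LEVELS):
            raise ConfigError(
                f"urbanicity_multipliers must cover {URBANICITY6_LEVELS}"
            )
        if set(self.race_shares) != set(RACE_LEVELS) or any(
            v <= 0 for v in self.race_shares.values()
        ):
            raise ConfigError("race_shares must be positive and cover all races")
        if not (0.9 < self.annual_improvement <= 1.1):
            raise ConfigError("annual_improvement must lie in (0.9, 1.1]")
        if self.counties_per_level < 1:
            raise ConfigError("need at least one county per urbanicity level")
        if self.years[1] < self.years[0]:
            raise ConfigError("year range is reversed")
        if self.county_pop_scale <= 0:
            raise ConfigError("county_pop_scale must be positive")


@dataclass(frozen=True)
class StudyBundle:
    """In-memory result of a scenario run, plus file paths when written."""

    counts: pd.DataFrame
    crosswalk: pd.DataFrame
    truth: pd.DataFrame
    counts_path: Path | None = None
    crosswalk_path: Path | None = None
    truth_path: Path | None = None


def _county_table(config: ScenarioConfig) -> pd.DataFrame:
    """county_fips + urbanicity6, either user-supplied or auto-numbered."""
    rows: list[tuple[str, str]] = []
    if config.county_fips is not None:
        for level in URBANICITY6_LEVELS:
            for fips in config.county_fips.get(level, ()):
                rows.append((str(fips), level))
    else:
        for i, level in enumerate(URBANICITY6_LEVELS):
            for j in range(config.counties_per_level):
                rows.append((f"{i + 1:02d}{j:03d}", level))
    table = pd.DataFrame(rows, columns=["county_fips", "urbanicity6"])
    dup = table["county_fips"].duplicated()
    if dup.any():
        raise ConfigError(
            "county identifiers overlap across urbanicity levels: "
            + ", ".join(sorted(table.loc[dup, "county_fips"]))
        )
    return table


def _truth_row(mx: np.ndarray, grid: AgeGrid) -> tuple[float, float, float]:
    cols = life_table_columns(mx[None, :], grid)
    e0 = float(cols["ex"][0, 0])
    _, sd = moments_from_columns(cols, grid, 0)
    sd0 = float(sd[0])
    return e0, sd0, sd0 / e0


def make_study_dataset(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    grid: AgeGrid = DEFAULT_GRID,
    step: float = 0.01,
) -> StudyBundle:
    """Generate the full counts/crosswalk/truth bundle for a scenario.

    Counts cover every year x county x age x gender x race cell.  Exposures
    are split across ages with the stationary-population age structure of each
    group's first-year schedule and held constant over calendar time; deaths
    are Poisson.  The truth table carries the abridged-grid e0, sd0 and cv0 of
    the exact expected pooled period rates, for race x gender cells at the
    6-level and 2-level urbanicity resolutions plus the race-pooled "ALL"
    rows.
    """
    rng = np.random.default_rng(config.seed)
    counties = _county_table(config)
    years = np.arange(config.years[0], config.years[1] + 1)
    K = grid.n_intervals
    labels = list(grid.labels)

    # one stable population size per county, log-normal around the scale
    county_pop = config.county_pop_scale * rng.lognormal(
        mean=0.0, sigma=config.county_pop_sigma, size=len(counties)
    )

    count_frames: list[pd.DataFrame] = []
    # expected pooled-period rate and exposure per (race, gender, level):
    # period label -> m̄_x; plus the constant age exposure N_x of the level
    group_period_mx: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
    group_exposure: dict[tuple[str, str, str], np.ndarray] = {}

    periods = [
        (lab, y0, y1)
        for (lab, y0, y1) in DEFAULT_PERIODS
        if not (y1 < years[0] or y0 > years[-1])
    ]

    for race in RACE_LEVELS:
        for gender in GENDER_LEVELS:
            for li, level in enumerate(URBANICITY6_LEVELS):
                mult = (
                    config.race_multipliers[race]
                    * config.gender_multipliers[gender]
                    * config.urbanicity_multipliers[level]
                )
                base = config.baseline.scaled(mult)
                m_by_year = np.vstack(
                    [
                        schedule_from_siler(
                            config.baseline.scaled(
                                mult * config.annual_improvement ** (y - years[0])
                            ),
                            grid,
                            step,
                        )
                        for y in years
                    ]
                )
                # stationary age structure of the first-year schedule
                cols0 = life_table_columns(m_by_year[0], grid)
                weights = cols0["Lx"] / cols0["Tx"][0]

                in_level = counties["urbanicity6"] == level
                pops = county_pop[in_level.to_numpy()]
                cell_pop = np.rint(
                    pops[:, None]
                    * config.race_shares[race]
                    * 0.5
                    * weights[None, :]
                ).astype(np.int64)  # (counties_in_level, K)

                lam = m_by_year[:, None, :] * cell_pop[None, :, :]
                deaths = rng.poisson(lam)  # (years, counties, K)

                nY, nC = len(years), cell_pop.shape[0]
                count_frames.append(
                    pd.DataFrame(
                        {
                            "year": np.repeat(years, nC * K),
                            "county_fips": np.tile(
                                np.repeat(
                                    counties.loc[in_level, "county_fips"].to_numpy(),
                                    K,
                                ),
                                nY,
                            ),
                            "age_group": np.tile(labels, nY * nC),
                            "gender": gender,
                            "race_ethnicity": race,
                            "deaths": deaths.reshape(-1),
                            "population": np.tile(cell_pop.reshape(-1), nY),
                        }
                    )
                )

                key = (race, gender, level)
                group_exposure[key] = cell_pop.sum(axis=0).astype(float)
                group_period_mx[key] = {}
                for lab, y0, y1 in periods:
                    in_period = (years >= y0) & (years <= y1)
                    group_period_mx[key][lab] = m_by_year[in_period].mean(axis=0)

    counts = pd.concat(count_frames, ignore_index=True)

    # ---- ground truth -----------------------------------------------------
    truth_rows: list[dict] = []

    def add_truth(race: str, gender: str, urb_label: str, lab: str, mx: np.ndarray):
        e0, sd0, cv0 = _truth_row(mx, grid)
        truth_rows.append(
            {
                "race_ethnicity": race,
                "gender": gender,
                "urbanicity": urb_label,
                "period": lab,
                "e0": e0,
                "sd0": sd0,
                "cv0": cv0,
            }
        )

    two_level = {
        "metropolitan": URBANICITY6_LEVELS[:4],
        "nonmetropolitan": URBANICITY6_LEVELS[4:],
    }
    for lab, _, _ in periods:
        for gender in GENDER_LEVELS:
            for race in RACE_LEVELS:
                for level in URBANICITY6_LEVELS:
                    add_truth(
                        race, gender, level, lab,
                        group_period_mx[(race, gender, level)][lab],
                    )
            # exposure-weighted pooling: 2-level and race-pooled rows
            for urb2, members in two_level.items():
                for race in RACE_LEVELS:
                    N = np.vstack(
                        [group_exposure[(race, gender, lv)] for lv in members]
                    )
                    M = np.vstack(
                        [group_period_mx[(race, gender, lv)][lab] for lv in members]
                    )
                    add_truth(
                        race, gender, urb2, lab,
                        (N * M).sum(axis=0) / N.sum(axis=0),
                    )
                N = np.vstack(
                    [
                        group_exposure[(race, gender, lv)]
                        for race in RACE_LEVELS
                        for lv in members
                    ]
                )
                M = np.vstack(
                    [
                        group_period_mx[(race, gender, lv)][lab]
                        for race in RACE_LEVELS
                        for lv in members
                    ]
                )
                add_truth(
                    "ALL", gender, urb2, lab, (N * M).sum(axis=0) / N.sum(axis=0)
                )

    truth = pd.DataFrame(truth_rows)

    bundle = StudyBundle(counts=counts, crosswalk=counties.copy(), truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cp, xp, tp = out / "counts.csv", out / "crosswalk.csv", out / "truth.csv"
        counts.to_csv(cp, index=False)
        counties.to_csv(xp, index=False)
        truth.to_csv(tp, index=False)
        logger.info(
            "wrote %d count rows for %d counties to %s",
            len(counts), len(counties), out,
        )
        bundle = replace(
            bundle, counts_path=cp, crosswalk_path=xp, truth_path=tp
        )
    return bundle
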