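"""Config-driven end-to-end runner.

simulate (or read) counts -> clean/pool -> life tables per stratum ->
lifespan variation -> bootstrap uncertainty -> inequality report, with a
machine-readable manifest.  Per-stratum bootstrap seeds are derived from the
root seed keyed by a CRC of the stratum label, so adding or removing strata
never reshuffles the draws of the others.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agegrid import AgeGrid, DEFAULT_GRID
from .errors import ConfigError, LifegapError
from .ingest import (
    apply_county_merges,
    apply_exclusions,
    compute_rates,
    excluded_fraction,
    map_urbanicity,
    pool_and_aggregate,
    read_counts,
    read_crosswalk,
    read_exclusions,
    read_merges,
)
from .lifetable import DEFAULT_A0, build_life_table, life_expectancy_at
from .synthetic import DEFAULT_PERIODS, ScenarioConfig, make_study_dataset
from .uncertainty import poisson_bootstrap
from .variation import cv_at_age, sd_at_age
from .inequality import inequality_report

__all__ = ["RunConfig", "RunResult", "run", "load_config"]

logger = logging.getLogger(__name__)

_KEY_COLS = ["race_ethnicity", "gender", "urbanicity", "period"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs.

    Either ``scenario`` (simulate) or ``counts``+``crosswalk`` (read files)
    must be provided.  ``ages`` are life-table start ages at which e, SD and
    CV are reported.
    """

    out_dir: Path
    scenario: ScenarioConfig | None = None
    counts: Path | None = None
    crosswalk: Path | None = None
    merges: Path | None = None
    exclusions: Path | None = None
    urbanicity_levels: int = 2
    ages: tuple[float, ...] = (0.0,)
    periods: tuple = DEFAULT_PERIODS
    bootstrap: bool = True
    bootstrap_reps: int = 1000
    seed: int = 20190101
    a0: float = DEFAULT_A0
    include_race_pooled: bool = True
    round_output: bool = False
    write_lifetables: bool = True

    def __post_init__(self) -> None:
        if self.scenario is None and (self.counts is None or self.crosswalk is None):
            raise ConfigError("provide a scenario to simulate or counts+crosswalk")
        if self.urbanicity_levels not in (2, 6):
            raise ConfigError("urbanicity_levels must be 2 or 6")
        if self.bootstrap and self.bootstrap_reps < 100:
            raise ConfigError("uncertainty needs at least 100 bootstrap replicates")
        for age in self.ages:
            DEFAULT_GRID.index_of(age)  # raises for non-grid ages


@dataclass(frozen=True)
class RunResult:
    results: pd.DataFrame
    inequality: pd.DataFrame
    manifest: dict
    out_dir: Path


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    scenario = raw.pop("scenario", None)
    if scenario is not None:
        baseline = scenario.pop("baseline", None)
        if baseline is not None:
            from .synthetic import SilerParams

            scenario["baseline"] = SilerParams(**baseline)
        for key in ("years",):
            if key in scenario:
                scenario[key] = tuple(scenario[key])
        scenario = ScenarioConfig(**scenario)
    for key in ("out_dir", "counts", "crosswalk", "merges", "exclusions"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    if "ages" in raw:
        raw["ages"] = tuple(float(a) for a in raw["ages"])
    try:
        return RunConfig(scenario=scenario, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _stratum_seed(root_seed: int, key: tuple) -> int:
    crc = zlib.crc32("|".join(str(k) for k in key).encode())
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(crc,))
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _safe_name(key: tuple) -> str:
    return "_".join(str(k) for k in key).replace("/", "-")


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle.

    Outputs under ``config.out_dir``: ``lifetables/<stratum>.csv`` (optional),
    ``results.csv`` (one row per stratum-period with e/sd/cv and bootstrap
    intervals at each requested age), ``inequality.csv``, ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if config.scenario is not None:
        bundle = make_study_dataset(config.scenario, out_dir=out / "inputs")
        counts = read_counts(bundle.counts_path)
        crosswalk = read_crosswalk(bundle.crosswalk_path)
    else:
        counts = read_counts(config.counts)
        crosswalk = read_crosswalk(config.crosswalk)

    hispanic_excluded = 0.0
    stage = "ingest"
    try:
        if config.merges is not None:
            counts = apply_county_merges(counts, read_merges(config.merges))
        if config.exclusions is not None:
            rules = read_exclusions(config.exclusions)
            hispanic_excluded = excluded_fraction(counts, rules, race="H")
            if not 0.0 <= hispanic_excluded <= 0.01:
                logger.warning(
                    "Hispanic exclusion fraction %.3f%% outside the expected "
                    "0-1%% band", 100 * hispanic_excluded,
                )
            counts = apply_exclusions(counts, rules)
        mapped = map_urbanicity(counts, crosswalk, levels=config.urbanicity_levels)
        pooled = pool_and_aggregate(mapped, periods=config.periods)
        if config.include_race_pooled:
            overall = (
                pooled.groupby(
                    ["gender", "urbanicity", "period", "age_group"],
                    as_index=False,
                    sort=False,
                )[["deaths", "person_years"]]
                .sum()
                .assign(race_ethnicity="ALL")
            )
            pooled = pd.concat([pooled, overall], ignore_index=True)
        stage = "rates"
        rates, dropped = compute_rates(pooled)
    except LifegapError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    # ---- per-stratum tables ----------------------------------------------
    if config.write_lifetables:
        (out / "lifetables").mkdir(exist_ok=True)
    rows: list[dict] = []
    for key, part in rates.groupby(_KEY_COLS, sort=True):
        stage_key = dict(zip(_KEY_COLS, key))
        try:
            mx = part["mx"].to_numpy(dtype=float)
            deaths = part["deaths"].to_numpy(dtype=np.int64)
            exposure = part["person_years"].to_numpy(dtype=float)
            table = build_life_table(mx, a0=config.a0)
            if config.write_lifetables:
                table.to_csv(
                    out / "lifetables" / f"{_safe_name(key)}.csv", index=False
                )
            row: dict = dict(stage_key)
            row["deaths_total"] = int(deaths.sum())
            row["person_years_total"] = float(exposure.sum())
            for age in config.ages:
                tag = f"{age:g}"
                res = cv_at_age(table, age)
                row[f"e{tag}"] = life_expectancy_at(table, age)
                row[f"sd{tag}"] = res.sd
                row[f"cv{tag}"] = res.cv
                if config.bootstrap:
                    bseed = _stratum_seed(config.seed, key + (tag,))
                    for stat in ("e", "cv"):
                        u = poisson_bootstrap(
                            deaths,
                            exposure,
                            stat=stat,
                            age=age,
                            reps=config.bootstrap_reps,
                            seed=bseed,
                            a0=config.a0,
                        )
                        row[f"{stat}{tag}_lo"] = u.lower
                        row[f"{stat}{tag}_hi"] = u.upper
                        row[f"se_{stat}{tag}"] = u.se
            rows.append(row)
        except LifegapError as exc:
            raise type(exc)(f"[stage lifetable, stratum {stage_key}] {exc}") from exc

    results = pd.DataFrame(rows)
    if config.bootstrap and len(results):
        results["reps"] = config.bootstrap_reps
        results["seed"] = config.seed

    measures = [
        f"{stat}{age:g}" for age in config.ages for stat in ("e", "sd", "cv")
    ]
    ineq = inequality_report(results, measures) if len(results) else pd.DataFrame()

    # ---- emit -------------------------------------------------------------
    results_out = results.copy()
    ineq_out = ineq.copy()
    if config.round_output:
        # presentation only: 1 decimal for years, 2 for dimensionless values
        cv_cols = [c for c in results_out.columns if c.startswith("cv")]
        year_cols = [
            c
            for c in results_out.columns
            if (c.startswith("e") or c.startswith("sd") or c.startswith("se_e"))
            and results_out[c].dtype.kind == "f"
        ]
        results_out[year_cols] = results_out[year_cols].round(1)
        results_out[cv_cols] = results_out[cv_cols].round(2)
        if len(ineq_out):
            ineq_out["absolute"] = ineq_out["absolute"].round(1)
            ineq_out["ratio"] = ineq_out["ratio"].round(2)
    results_out.to_csv(out / "results.csv", index=False)
    ineq_out.to_csv(out / "inequality.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "urbanicity_levels": config.urbanicity_levels,
        "ages": list(config.ages),
        "bootstrap_reps": config.bootstrap_reps if config.bootstrap else 0,
        "strata": int(len(results)),
        "dropped_strata": [list(k) for k in dropped],
        "hispanic_excluded_fraction": hispanic_excluded,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(results=results, inequality=ineq, manifest=manifest, out_dir=out)
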