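import numpy as np
import pandas as pd
import pytest

from lifegap import ConfigError, DataError, IntegrityError, MappingError, ParseError
from lifegap.agegrid import AGE_GROUP_LABELS, DEFAULT_GRID
from lifegap.ingest import (
    METRO_COLLAPSE,
    apply_county_merges,
    apply_exclusions,
    compute_rates,
    excluded_fraction,
    map_urbanicity,
    pool_and_aggregate,
    read_counts,
    read_crosswalk,
)

K = DEFAULT_GRID.n_intervals


def toy_counts(fips="22001", year=1990, race="H", deaths=3, pop=1000):
    """One full stratum (all age groups) for a single county-year."""
    return pd.DataFrame(
        {
            "year": year,
            "county_fips": fips,
            "age_group": AGE_GROUP_LABELS,
            "gender": "man",
            "race_ethnicity": race,
            "deaths": deaths,
            "population": pop,
        }
    )


class TestReadCounts:
    def test_round_trip_preserves_rows_and_totals(self, small_bundle):
        table = read_counts(small_bundle.counts_path)
        assert len(table) == len(small_bundle.counts)
        assert table["deaths"].sum() == small_bundle.counts["deaths"].sum()
        assert table["population"].sum() == small_bundle.counts["population"].sum()

    def test_unknown_age_label_rejected(self, tmp_path, small_bundle):
        bad = small_bundle.counts.copy()
        bad.loc[7, "age_group"] = "85plus"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ParseError, match="85plus"):
            read_counts(path)

    def test_duplicated_cell_rejected(self, tmp_path, small_bundle):
        dup = pd.concat(
            [small_bundle.counts, small_bundle.counts.iloc[[4]]],
            ignore_index=True,
        )
        path = tmp_path / "dup.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(IntegrityError):
            read_counts(path)

    def test_negative_count_rejected_with_line_number(self, tmp_path, small_bundle):
        bad = small_bundle.counts.copy()
        bad.loc[2, "deaths"] = -1
        path = tmp_path / "neg.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ParseError, match="line"):
            read_counts(path)


class TestCountyMerges:
    def test_empty_map_is_identity(self):
        table = toy_counts()
        merged = apply_county_merges(table, pd.DataFrame(columns=["old_fips", "new_fips"]))
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), table.reset_index(drop=True)
        )

    def test_merged_counties_sum_cellwise_and_conserve_totals(self):
        a, b = toy_counts("22001", deaths=3), toy_counts("22003", deaths=5)
        table = pd.concat([a, b], ignore_index=True)
        merges = pd.DataFrame({"old_fips": ["22003"], "new_fips": ["22001"]})
        merged = apply_county_merges(table, merges)
        assert set(merged["county_fips"]) == {"22001"}
        assert (merged["deaths"] == 8).all()
        assert merged["deaths"].sum() == table["deaths"].sum()
        assert merged["population"].sum() == table["population"].sum()


class TestExclusions:
    RULES = pd.DataFrame(
        {
            "state_prefix": ["22", "33", "40"],
            "year_start": [1990, 1990, 1990],
            "year_end": [1990, 1992, 1996],
            "race_ethnicity": ["H", "H", "H"],
        }
    )

    def test_matching_rows_removed_and_neighbours_kept(self):
        table = pd.concat(
            [
                toy_counts("22001", 1990, "H"),    # removed: LA-style 1990
                toy_counts("22001", 1991, "H"),    # kept: outside year range
                toy_counts("22001", 1990, "NHW"),  # kept: other race
                toy_counts("33001", 1992, "H"),    # removed: NH-style 1990-92
            ],
            ignore_index=True,
        )
        out = apply_exclusions(table, self.RULES)
        kept = set(zip(out["county_fips"], out["year"], out["race_ethnicity"]))
        assert ("22001", 1990, "H") not in kept
        assert ("22001", 1991, "H") in kept
        assert ("22001", 1990, "NHW") in kept
        assert ("33001", 1992, "H") not in kept

    def test_empty_match_is_identity(self):
        table = toy_counts("06001", 2015, "H")
        out = apply_exclusions(table, self.RULES)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), table.reset_index(drop=True)
        )

    def test_removed_fraction_is_small_under_realistic_state_weights(self):
        # a 50-state-like layout where the three excluded states hold well
        # under 1% of Hispanic person-years in the affected years
        frames = [
            toy_counts(f"{s:02d}001", 1990, "H", pop=10_000)
            for s in range(1, 51)
            if s not in (22, 33, 40)
        ]
        for fips, pop in (("22001", 800), ("33001", 600), ("40001", 700)):
            frames.append(toy_counts(fips, 1990, "H", pop=pop))
        table = pd.concat(frames, ignore_index=True)
        frac = excluded_fraction(table, self.RULES, race="H")
        assert 0.0 < frac < 0.01


class TestUrbanicityMapping:
    CROSSWALK = pd.DataFrame(
        {
            "county_fips": ["10001", "10002", "10003"],
            "urbanicity6": ["noncore", "medium", "large_central"],
        }
    )

    def test_two_level_collapse(self):
        table = pd.concat(
            [toy_counts("10001"), toy_counts("10002")], ignore_index=True
        )
        out = map_urbanicity(table, self.CROSSWALK, levels=2)
        lookup = dict(zip(out["county_fips"], out["urbanicity"]))
        assert lookup["10001"] == "nonmetropolitan"  # noncore
        assert lookup["10002"] == "metropolitan"     # medium

    def test_six_level_passthrough(self):
        out = map_urbanicity(toy_counts("10003"), self.CROSSWALK, levels=6)
        assert set(out["urbanicity"]) == {"large_central"}

    def test_unmapped_county_raises_with_fips(self):
        with pytest.raises(MappingError, match="99999"):
            map_urbanicity(toy_counts("99999"), self.CROSSWALK, levels=2)


class TestPooling:
    def _with_urbanicity(self, table):
        out = table.copy()
        out["urbanicity"] = "metropolitan"
        return out

    def test_single_year_single_county_is_identity_on_counts(self):
        table = self._with_urbanicity(toy_counts(year=2015, deaths=4, pop=900))
        pooled = pool_and_aggregate(table)
        assert (pooled["deaths"] == 4).all()
        assert (pooled["person_years"] == 900).all()
        assert set(pooled["period"]) == {"2015-2019"}

    def test_five_identical_years_give_five_fold_counts(self):
        years = [toy_counts(year=y, deaths=2, pop=500) for y in range(2015, 2020)]
        table = self._with_urbanicity(pd.concat(years, ignore_index=True))
        pooled = pool_and_aggregate(table)
        assert (pooled["deaths"] == 10).all()
        assert (pooled["person_years"] == 2500).all()

    def test_year_outside_all_periods_is_a_config_error(self):
        table = self._with_urbanicity(toy_counts(year=1985))
        with pytest.raises(ConfigError):
            pool_and_aggregate(table)

    def test_pooled_totals_match_generator_bookkeeping(self, small_bundle):
        table = read_counts(small_bundle.counts_path)
        mapped = map_urbanicity(table, read_crosswalk(small_bundle.crosswalk_path), 2)
        pooled = pool_and_aggregate(mapped)
        assert pooled["deaths"].sum() == small_bundle.counts["deaths"].sum()
        assert pooled["person_years"].sum() == small_bundle.counts["population"].sum()

    def test_aggregation_commutes_with_urbanicity_collapse(self, small_bundle):
        table = read_counts(small_bundle.counts_path)
        crosswalk = read_crosswalk(small_bundle.crosswalk_path)
        direct = pool_and_aggregate(map_urbanicity(table, crosswalk, levels=2))
        six = pool_and_aggregate(map_urbanicity(table, crosswalk, levels=6))
        six["urbanicity"] = six["urbanicity"].map(METRO_COLLAPSE)
        collapsed = (
            six.groupby(
                ["race_ethnicity", "gender", "urbanicity", "period", "age_group"],
                as_index=False,
                sort=False,
            )[["deaths", "person_years"]]
            .sum()
        )
        key = ["race_ethnicity", "gender", "urbanicity", "period", "age_group"]
        pd.testing.assert_frame_equal(
            direct.sort_values(key).reset_index(drop=True),
            collapsed.sort_values(key).reset_index(drop=True),
        )


class TestRates:
    def _pooled_stratum(self, deaths, person_years):
        return pd.DataFrame(
            {
                "race_ethnicity": "NHW",
                "gender": "man",
                "urbanicity": "metropolitan",
                "period": "2015-2019",
                "age_group": AGE_GROUP_LABELS,
                "deaths": deaths,
                "person_years": person_years,
            }
        )

    def test_rate_is_deaths_over_person_years(self):
        pooled = self._pooled_stratum(20, 1000)
        rates, dropped = compute_rates(pooled)
        assert dropped == []
        assert rates["mx"].to_numpy() == pytest.approx(0.02)

    def test_zero_deaths_legal_in_closed_intervals(self):
        deaths = np.full(K, 5)
        deaths[3] = 0
        rates, dropped = compute_rates(self._pooled_stratum(deaths, 1000))
        assert dropped == []
        assert rates.loc[3, "mx"] == 0.0

    def test_no_open_interval_deaths_flags_stratum_unusable(self):
        deaths = np.full(K, 5)
        deaths[-1] = 0
        rates, dropped = compute_rates(self._pooled_stratum(deaths, 1000))
        assert len(rates) == 0
        assert dropped == [("NHW", "man", "metropolitan", "2015-2019")]

    def test_deaths_with_zero_exposure_is_a_data_error(self):
        py = np.full(K, 1000)
        py[4] = 0
        with pytest.raises(DataError):
            compute_rates(self._pooled_stratum(5, py))
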