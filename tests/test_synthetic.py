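import numpy as np
import pytest

from lifegap import (
    ConfigError,
    DEFAULT_GRID,
    DomainError,
    ScenarioConfig,
    SilerParams,
    continuous_moments,
    make_study_dataset,
    sample_lifetimes,
    schedule_from_siler,
    simulate_counts,
    siler_hazard,
)

K = DEFAULT_GRID.n_intervals

CONSTANT = SilerParams(a1=0.0, b1=1.0, c=0.02, a2=0.0, b2=0.1)


class TestHazard:
    def test_constant_reduction(self):
        assert siler_hazard(SilerParams(0, 1, 0.02, 0, 0.1), 30) == pytest.approx(0.02)

    def test_only_infant_term_at_birth(self):
        assert siler_hazard(SilerParams(0.05, 2, 0, 0, 0.1), 0) == pytest.approx(0.05)

    def test_three_term_sum(self):
        p = SilerParams(a1=0.01, b1=1, c=0.001, a2=0.0001, b2=0.09)
        expected = 0.01 * np.exp(-80.0) + 0.001 + 0.0001 * np.exp(0.09 * 80)
        assert siler_hazard(p, 80) == pytest.approx(expected, rel=1e-12)

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            siler_hazard(CONSTANT, -1)

    def test_negative_parameters_rejected(self):
        with pytest.raises(DomainError):
            SilerParams(a1=-0.01, b1=1, c=0.01, a2=0, b2=0)

    def test_improper_schedule_cannot_be_integrated(self):
        # infant-only hazard: 2.5% of the cohort never dies
        with pytest.raises(DomainError):
            continuous_moments(SilerParams(a1=0.05, b1=2, c=0, a2=0, b2=0.1))


class TestScheduleFromSiler:
    def test_constant_hazard_is_its_own_central_rate(self):
        mx = schedule_from_siler(CONSTANT)
        np.testing.assert_allclose(mx, 0.02, atol=1e-6)

    def test_rates_are_nonnegative(self, random_schedules):
        for _, mx in random_schedules[:5]:
            assert (mx >= 0).all()

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ConfigError):
            schedule_from_siler(CONSTANT, step=0.0)

    def test_old_age_rate_matches_lifetime_simulation(self):
        """m for [80,85) equals deaths/person-years of simulated lifetimes."""
        params = SilerParams(a1=0.01, b1=1.3, c=5e-4, a2=3e-5, b2=0.1)
        mx = schedule_from_siler(params)
        rng = np.random.default_rng(2024)
        t = sample_lifetimes(params, 10**6, rng)
        py = np.clip(t - 80.0, 0.0, 5.0).sum()
        deaths = ((t >= 80.0) & (t < 85.0)).sum()
        se = np.sqrt(deaths) / py
        idx = DEFAULT_GRID.index_of(80)
        assert mx[idx] == pytest.approx(deaths / py, abs=3 * se)


class TestContinuousMoments:
    def test_exponential_closed_form(self):
        e0, sd0 = continuous_moments(CONSTANT)
        assert e0 == pytest.approx(50.0, rel=1e-4)
        assert sd0 == pytest.approx(50.0, rel=1e-3)

    def test_matches_mean_of_simulated_lifetimes(self, random_schedules):
        rng = np.random.default_rng(7)
        params, _ = random_schedules[0]
        e0, _ = continuous_moments(params)
        sim = sample_lifetimes(params, 10**6, rng)
        assert abs(e0 - sim.mean()) < 0.05


class TestSimulateCounts:
    def test_zero_rates_give_zero_deaths(self):
        deaths = simulate_counts(np.zeros(K), np.full(K, 1e5), seed=1)
        assert (deaths == 0).all()

    def test_deterministic_under_seed(self, constant_schedule):
        a = simulate_counts(constant_schedule, np.full(K, 1e5), seed=5)
        b = simulate_counts(constant_schedule, np.full(K, 1e5), seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rate_recovery_within_three_standard_errors(self):
        n = 1e6
        deaths = simulate_counts(np.full(K, 0.02), np.full(K, n), seed=11)
        se = np.sqrt(0.02 / n)
        assert np.all(np.abs(deaths / n - 0.02) < 3 * se + 1e-12)

    def test_negative_exposure_rejected(self, constant_schedule):
        with pytest.raises(DomainError):
            simulate_counts(constant_schedule, np.full(K, -1.0), seed=1)


class TestStudyDataset:
    def test_cell_count_per_county_year(self):
        cfg = ScenarioConfig(
            baseline=CONSTANT,
            years=(2015, 2015),
            counties_per_level=1,
            county_pop_scale=10_000,
            seed=3,
        )
        bundle = make_study_dataset(cfg)
        per_county_year = bundle.counts.groupby(["county_fips", "year"]).size()
        assert (per_county_year == K * 2 * 4).all()

    def test_constant_hazard_truth_is_exponential(self):
        cfg = ScenarioConfig(
            baseline=CONSTANT,
            race_multipliers={r: 1.0 for r in ("H", "NHW", "NHB", "NHAPI")},
            gender_multipliers={"man": 1.0, "woman": 1.0},
            urbanicity_multipliers={
                u: 1.0
                for u in (
                    "large_central", "large_fringe", "medium",
                    "small", "micropolitan", "noncore",
                )
            },
            annual_improvement=1.0,
            years=(2015, 2015),
            counties_per_level=1,
            county_pop_scale=10_000,
            seed=3,
        )
        truth = make_study_dataset(cfg).truth
        assert truth["e0"].to_numpy() == pytest.approx(50.0, abs=0.5)
        assert truth["cv0"].to_numpy() == pytest.approx(1.0, abs=0.03)

    def test_raising_a_multiplier_lowers_truth_e0(self):
        base = ScenarioConfig(years=(2015, 2015), counties_per_level=1, seed=3)
        worse_black = ScenarioConfig(
            years=(2015, 2015),
            counties_per_level=1,
            seed=3,
            race_multipliers={"H": 0.82, "NHW": 1.0, "NHB": 1.9, "NHAPI": 0.55},
        )
        t0 = make_study_dataset(base).truth.set_index(
            ["race_ethnicity", "gender", "urbanicity", "period"]
        )
        t1 = make_study_dataset(worse_black).truth.set_index(
            ["race_ethnicity", "gender", "urbanicity", "period"]
        )
        nhb = t0.index.get_level_values(0) == "NHB"
        assert (t1.loc[nhb, "e0"] < t0.loc[nhb, "e0"]).all()
        nhw = t0.index.get_level_values(0) == "NHW"
        assert t1.loc[nhw, "e0"].to_numpy() == pytest.approx(
            t0.loc[nhw, "e0"].to_numpy(), rel=1e-12
        )

    def test_reproducible_under_seed(self):
        cfg = ScenarioConfig(years=(2015, 2016), counties_per_level=1, seed=77)
        a = make_study_dataset(cfg)
        b = make_study_dataset(cfg)
        assert a.counts.equals(b.counts)
        assert a.truth.equals(b.truth)

    def test_overlapping_county_ids_rejected(self):
        cfg = ScenarioConfig(
            years=(2015, 2015),
            counties_per_level=1,
            county_fips={
                "large_central": ("01001",),
                "large_fringe": ("01001",),
                "medium": ("01002",),
                "small": ("01003",),
                "micropolitan": ("01004",),
                "noncore": ("01005",),
            },
        )
        with pytest.raises(ConfigError):
            make_study_dataset(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(annual_improvement=0.5)
        with pytest.raises(ConfigError):
            ScenarioConfig(counties_per_level=0)
        with pytest.raises(ConfigError):
            ScenarioConfig(gender_multipliers={"man": -1.0, "woman": 1.0})
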