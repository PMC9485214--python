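import numpy as np
import pytest

from lifegap import DEFAULT_GRID, ScenarioConfig, make_study_dataset, random_siler_params
from lifegap.synthetic import schedule_from_siler

K = DEFAULT_GRID.n_intervals


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture()
def constant_schedule():
    """Constant hazard 0.02/yr: the exponential closed-form oracle."""
    return np.full(K, 0.02)


@pytest.fixture(scope="session")
def random_schedules():
    """30 plausible human Siler schedules with their abridged rates."""
    rng = np.random.default_rng(42)
    params = [random_siler_params(rng) for _ in range(30)]
    return [(p, schedule_from_siler(p)) for p in params]


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact written study bundle: 1 county per level, one 5-yr period."""
    cfg = ScenarioConfig(
        years=(2015, 2019),
        counties_per_level=1,
        county_pop_scale=30_000,
        seed=123,
    )
    out = tmp_path_factory.mktemp("bundle")
    return make_study_dataset(cfg, out_dir=out)
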