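import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import organcarbon as oc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231130)


@pytest.fixture(scope="session")
def toy_window():
    """A short 2-year window: 12 pre months, 13 post months (impl month
    included), implementation 2020-01-15."""
    cal = oc.PolicyCalendar(
        implementation_dates={"heart": dt.date(2020, 1, 15)},
        study_end=dt.date(2021, 1, 31),
    )
    return oc.build_window("heart", cal)


def make_spec(**overrides):
    """A small, fast heart-like cohort spec with sensible defaults."""
    base = dict(
        organ="heart",
        implementation_date=dt.date(2020, 1, 15),
        study_end=dt.date(2021, 1, 31),
        monthly_volume=5,
        baseline_mean_miles=200.0,
        pre_slope_miles_per_month=-0.5,
        level_change_miles=80.0,
        post_slope_miles_per_month=2.0,
        trip_noise=0.0,
        seed=11,
    )
    base.update(overrides)
    return oc.CohortSpec(**base)


@pytest.fixture()
def small_spec():
    return make_spec()


@pytest.fixture(scope="session")
def noise_free_heart():
    """Deceased-only, noise-free heart cohort resolved end to end."""
    spec = make_spec(monthly_volume=6)
    records, gaz = oc.generate_cohort(spec)
    kept, _ = oc.filter_cohort(records, spec.window)
    trips, _ = oc.resolve_trips(kept, gaz)
    series = oc.aggregate_monthly(trips, spec.window)
    return spec, trips, series


def normal_equations_fit(series):
    """Independent segmented-OLS oracle: explicit normal-equations solve."""
    obs = series.nonempty()
    m = obs.index.to_numpy(dtype=float)
    post = obs["is_post"].to_numpy(dtype=float)
    elapsed = obs["elapsed_post"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(m), m, post, post * elapsed])
    y = obs["mean_distance"].to_numpy(dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta  # [intercept, pre_slope, level_change, slope_change]
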