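"""Travel-mode scenarios and emission accounting."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

import organcarbon as oc
from conftest import make_spec

FACTORS = oc.EmissionFactors()


def test_assign_mode_rules():
    s100 = oc.ModeScenario(threshold=100.0)
    assert oc.assign_mode(150.0, "liver", s100) == "charter"
    assert oc.assign_mode(300.0, "kidney", oc.ModeScenario(threshold=200.0)) == "commercial"
    assert oc.assign_mode(50.0, "heart", s100) == "drive"
    # ties drive: the rule is strictly greater-than
    for organ in oc.ORGANS:
        assert oc.assign_mode(100.0, organ, s100) == "drive"
    with pytest.raises(KeyError):
        oc.assign_mode(10.0, "pancreas", s100)


def test_trip_emissions_linearity_and_zero_cases():
    assert oc.trip_emissions(5000.0, "commercial", FACTORS) == 0.0
    assert oc.trip_emissions(0.0, "charter", FACTORS) == 0.0
    f = FACTORS.drive_kg_per_mile
    assert oc.trip_emissions(100.0, "drive", FACTORS) == pytest.approx(100.0 * f)
    # homogeneous of degree 1 in distance
    assert oc.trip_emissions(250.0, "charter", FACTORS) == pytest.approx(
        2.5 * oc.trip_emissions(100.0, "charter", FACTORS)
    )


def _trips(rows, organ="heart"):
    return pd.DataFrame(
        [(f"r{i}", organ, d, x, "f") for i, (d, x) in enumerate(rows)],
        columns=["record_id", "organ", "transplant_date", "distance_miles", "resolution_flags"],
    )


def _cohort(organ="heart", seed=17, noise=0.5, volume=25):
    spec = make_spec(organ=organ, trip_noise=noise, monthly_volume=volume, seed=seed)
    records, gaz = oc.generate_cohort(spec)
    kept, _ = oc.filter_cohort(records, spec.window)
    trips, _ = oc.resolve_trips(kept, gaz)
    series = oc.aggregate_monthly(trips, spec.window)
    fit = oc.fit_its(series)
    months = pd.PeriodIndex(pd.to_datetime(trips["transplant_date"]), freq="M")
    post = months >= spec.window.implementation_month
    return spec, trips[post], series, fit, trips[~post]


def brute_force_excess(trips_post, series, fit, scenario, factors, trips_pre,
                       reassign_modes=False):
    """Per-trip enumeration oracle (pure Python loop)."""
    window = series.window
    total_post = counterfactual = pre = 0.0
    for row in trips_post.itertuples(index=False):
        m = window.month_index(row.transplant_date)
        observed_mean = series.table.loc[m, "mean_distance"]
        predicted_mean = fit.intercept + fit.pre_slope * m
        d = row.distance_miles
        s = d * predicted_mean / observed_mean
        mode_d = oc.assign_mode(d, row.organ, scenario)
        mode_s = oc.assign_mode(s, row.organ, scenario) if reassign_modes else mode_d
        total_post += oc.trip_emissions(d, mode_d, factors)
        counterfactual += oc.trip_emissions(s, mode_s, factors)
    for row in trips_pre.itertuples(index=False):
        mode = oc.assign_mode(row.distance_miles, row.organ, scenario)
        pre += oc.trip_emissions(row.distance_miles, mode, factors)
    return total_post, counterfactual, pre


@pytest.mark.parametrize("reassign", [False, True])
def test_excess_emissions_matches_per_trip_enumeration(reassign):
    spec, post, series, fit, pre = _cohort(volume=10)
    scenario = oc.ModeScenario(threshold=100.0)
    result = oc.excess_emissions(post, series, fit, scenario, FACTORS, pre,
                                 reassign_modes=reassign)
    t, c, p = brute_force_excess(post, series, fit, scenario, FACTORS, pre,
                                 reassign_modes=reassign)
    assert result.total_post_emissions == pytest.approx(t, rel=1e-9)
    assert result.counterfactual_post_emissions == pytest.approx(c, rel=1e-9)
    assert result.pre_emissions == pytest.approx(p, rel=1e-9)


def test_excess_zero_under_null_effect():
    # a null cohort: observed post means continue the pre trend exactly
    null_spec = make_spec(level_change_miles=0.0, post_slope_miles_per_month=-0.5,
                          monthly_volume=10, seed=5)
    records, gaz = oc.generate_cohort(null_spec)
    trips, _ = oc.resolve_trips(records, gaz)
    series = oc.aggregate_monthly(trips, null_spec.window)
    fit = oc.fit_its(series)
    months = pd.PeriodIndex(pd.to_datetime(trips["transplant_date"]), freq="M")
    post_mask = months >= null_spec.window.implementation_month
    result = oc.excess_emissions(
        trips[post_mask], series, fit, oc.ModeScenario(threshold=100.0), FACTORS,
        trips[~post_mask],
    )
    assert result.excess_emissions == pytest.approx(0.0, abs=1e-6)


def test_conservation_exact():
    _, post, series, fit, pre = _cohort()
    for thr in oc.DEFAULT_THRESHOLDS:
        r = oc.excess_emissions(post, series, fit, oc.ModeScenario(threshold=thr),
                                FACTORS, pre)
        assert r.excess_emissions + r.counterfactual_post_emissions == r.total_post_emissions


def test_threshold_monotonicity_matches_organ_class():
    """Charter-organ excess falls with threshold, kidney's rises."""
    for organ, direction in (("heart", -1), ("kidney", +1)):
        _, post, series, fit, pre = _cohort(organ=organ, volume=50, noise=0.4)
        grid = oc.scenario_grid(post, series, fit, FACTORS, pre)
        values = [grid[t].excess_emissions for t in sorted(grid)]
        diffs = np.diff(values)
        assert np.all(direction * diffs >= -1e-9), (organ, values)


def test_scenario_emissions_derived_fields():
    _, post, series, fit, pre = _cohort(volume=10)
    r = oc.excess_emissions(post, series, fit, oc.ModeScenario(threshold=50.0),
                            FACTORS, pre)
    assert r.n_post_transplants == len(post)
    assert r.excess_per_organ == pytest.approx(r.excess_emissions / len(post))
    assert r.pct_increase_over_pre == pytest.approx(
        100.0 * r.excess_emissions / r.pre_emissions
    )


# --- composition bounds -------------------------------------------------


def _toy_grid():
    thresholds = list(oc.DEFAULT_THRESHOLDS)
    data = {
        "heart": [60.0, 55.0, 40.0, 30.0, 20.0],
        "lung": [30.0, 28.0, 20.0, 15.0, 10.0],
        "liver": [45.0, 42.0, 35.0, 25.0, 18.0],
        "kidney": [1.0, 2.0, 5.0, 9.0, 14.0],
    }
    return pd.DataFrame(data, index=pd.Index(thresholds, name="threshold"))


def test_compose_bounds_brackets_all_compositions():
    grid = _toy_grid()
    bounds = oc.compose_bounds(grid)
    totals = [
        sum(grid.loc[t, organ] for organ, t in zip(grid.columns, combo))
        for combo in itertools.product(grid.index, repeat=len(grid.columns))
    ]
    assert bounds["most_liberal_total"] == pytest.approx(max(totals))
    assert bounds["most_conservative_total"] == pytest.approx(min(totals))


def test_compose_bounds_zero_and_single_organ():
    zero = _toy_grid() * 0.0
    b = oc.compose_bounds(zero)
    assert b["most_liberal_total"] == b["most_conservative_total"] == 0.0
    heart_only = _toy_grid()[["heart"]]
    b = oc.compose_bounds(heart_only)
    assert b["most_liberal_total"] == 60.0
    assert b["most_conservative_total"] == 20.0


def test_compose_bounds_missing_cells_error():
    grid = _toy_grid()
    grid.loc[100.0, "liver"] = np.nan
    with pytest.raises(ValueError):
        oc.compose_bounds(grid)


# --- distance proportions ------------------------------------------------


def test_proportion_under_counting(toy_window):
    trips = _trips(
        [
            (dt.date(2019, 5, 1), 30.0),
            (dt.date(2019, 6, 1), 60.0),
            (dt.date(2019, 7, 1), 90.0),
            (dt.date(2020, 6, 1), 10.0),
        ]
    )
    out = oc.proportion_under(trips, 50.0, toy_window)
    assert out["pre"]["overall"] == pytest.approx(1 / 3)
    assert out["post"]["overall"] == pytest.approx(1.0)


def test_proportion_under_empty_group_is_undefined(toy_window):
    trips = _trips([(dt.date(2019, 5, 1), 30.0)])
    out = oc.proportion_under(trips, 50.0, toy_window)
    assert out["post"]["overall"] is None


def test_proportion_under_matches_brute_force(toy_window, rng):
    dates = [dt.date(2019 + int(rng.integers(0, 2)), int(rng.integers(1, 13)), 10) for _ in range(100)]
    dists = rng.gamma(2.0, 80.0, size=100)
    trips = _trips(list(zip(dates, dists)))
    trips["region"] = [f"Region {1 + i % 3}" for i in range(100)]
    out = oc.proportion_under(trips, 75.0, toy_window, group_by="region")
    impl = toy_window.implementation_month
    for phase, cmp in (("pre", lambda p: p < impl), ("post", lambda p: p >= impl)):
        sel = [cmp(pd.Period(d, freq="M")) for d in dates]
        n = sum(sel)
        k = sum(1 for s, x in zip(sel, dists) if s and x < 75.0)
        assert out[phase]["overall"] == pytest.approx(k / n)
        for g in ("Region 1", "Region 2", "Region 3"):
            gs = [s and r == g for s, r in zip(sel, trips["region"])]
            ng = sum(gs)
            kg = sum(1 for s, x in zip(gs, dists) if s and x < 75.0)
            expected = kg / ng if ng else None
            if expected is None:
                assert out[phase]["by_group"][g] is None
            else:
                assert out[phase]["by_group"][g] == pytest.approx(expected)
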