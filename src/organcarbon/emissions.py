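"""Travel-mode scenarios and transport carbon-emission accounting.

Because mode of travel is not recorded in the registry, each trip's mode
is imputed from its distance under a grid of threshold scenarios: an
organ flies if its trip distance strictly exceeds the scenario threshold
(25, 50, 100, 150 or 200 miles) and is driven otherwise. Hearts, lungs
and livers fly by dedicated charter; kidneys fly on scheduled commercial
flights, which carry no attributed emissions — so for kidneys the
higher-threshold scenarios (more driving) are the *conservative* ones,
the reverse of the charter organs.

Excess emissions compare the observed post-period trips against a
counterfactual fleet in which each post trip's distance is rescaled by
the ratio of the month's counterfactual (pre-trend) mean to its observed
mean. By default each trip keeps the mode imputed at its observed
distance, so the excess is the per-mode carbon intensity applied to the
excess miles; re-imputing modes at the rescaled distances is available
as a sensitivity (``reassign_modes=True``), but note it breaks the
threshold monotonicity of the scenario table (a shortened trip that
drops below the threshold swaps a cheap drive in for an expensive
charter, inflating the excess at higher thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ObservationWindow
from .config import CHARTER_ORGANS, DEFAULT_THRESHOLDS, ORGANS, EmissionFactors
from .its import ITSFit, MonthlySeries

MODES = ("drive", "charter", "commercial")


@dataclass(frozen=True)
class ModeScenario:
    """One cell of the travel-mode assumption grid.

    ``threshold`` is in miles; trips strictly longer fly, ties drive.
    ``fly_mode_by_organ`` defaults to charter for heart/lung/liver and
    commercial for kidney.
    """

    threshold: float
    fly_mode_by_organ: dict[str, str] = field(
        default_factory=lambda: {
            organ: ("charter" if organ in CHARTER_ORGANS else "commercial")
            for organ in ORGANS
        }
    )
    ground_mode: str = "drive"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        for organ, mode in self.fly_mode_by_organ.items():
            if mode not in MODES:
                raise ValueError(f"unknown fly mode {mode!r} for {organ}")


def assign_mode(distance: float, organ: str, scenario: ModeScenario) -> str:
    """Impute the travel mode of one trip: fly iff distance > threshold."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    try:
        fly_mode = scenario.fly_mode_by_organ[organ]
    except KeyError:
        raise KeyError(f"no fly mode configured for organ {organ!r}") from None
    return fly_mode if distance > scenario.threshold else scenario.ground_mode


def trip_emissions(distance: float, mode: str, factors: EmissionFactors) -> float:
    """kg CO2e for one trip: distance times the per-mile mode factor."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return distance * factors.factor(mode)


def _mode_factors(
    distances: np.ndarray, organ: str, scenario: ModeScenario, factors: EmissionFactors
) -> np.ndarray:
    """Per-trip emission factor (kg CO2e/mi) under the scenario's mode rule."""
    fly = np.asarray(distances, dtype=float) > scenario.threshold
    fly_factor = factors.factor(scenario.fly_mode_by_organ[organ])
    ground_factor = factors.factor(scenario.ground_mode)
    return np.where(fly, fly_factor, ground_factor)


def _fleet_emissions(
    distances: np.ndarray, organ: str, scenario: ModeScenario, factors: EmissionFactors
) -> float:
    """Total kg CO2e over an array of trip distances (vectorized)."""
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0):
        raise ValueError("distances must be >= 0")
    return float(np.sum(distances * _mode_factors(distances, organ, scenario, factors)))


@dataclass(frozen=True)
class ScenarioEmissions:
    """Emission accounting for one organ under one mode scenario."""

    organ: str
    threshold: float
    total_post_emissions: float
    counterfactual_post_emissions: float
    pre_emissions: float
    n_post_transplants: int

    @property
    def excess_emissions(self) -> float:
        return self.total_post_emissions - self.counterfactual_post_emissions

    @property
    def excess_per_organ(self) -> float:
        if self.n_post_transplants == 0:
            return float("nan")
        return self.excess_emissions / self.n_post_transplants

    @property
    def pct_increase_over_pre(self) -> float:
        if self.pre_emissions == 0:
            return float("nan")
        return 100.0 * self.excess_emissions / self.pre_emissions

    def as_dict(self) -> dict:
        return {
            "organ": self.organ,
            "threshold": self.threshold,
            "total_post_emissions": self.total_post_emissions,
            "counterfactual_post_emissions": self.counterfactual_post_emissions,
            "pre_emissions": self.pre_emissions,
            "excess_emissions": self.excess_emissions,
            "n_post_transplants": self.n_post_transplants,
            "excess_per_organ": self.excess_per_organ,
            "pct_increase_over_pre": self.pct_increase_over_pre,
        }


def _split_pre_post(trips: pd.DataFrame, window: ObservationWindow):
    months = pd.PeriodIndex(pd.to_datetime(trips["transplant_date"]), freq="M")
    is_post = months >= window.implementation_month
    return trips[~is_post], trips[is_post], months


def excess_emissions(
    trips_post: pd.DataFrame,
    series: MonthlySeries,
    fit: ITSFit,
    scenario: ModeScenario,
    factors: EmissionFactors,
    trips_pre: pd.DataFrame,
    reassign_modes: bool = False,
) -> ScenarioEmissions:
    """Scenario emission accounting for one organ window.

    * ``total_post_emissions``: observed post trips, modes imputed at
      their observed distances.
    * ``counterfactual_post_emissions``: the same trips with each
      distance rescaled by (counterfactual mean / observed mean) of its
      calendar month. Modes stay as imputed at the observed distance
      unless ``reassign_modes=True``, which re-imputes them at the
      rescaled distance (sensitivity only; see module docstring).
    * ``pre_emissions``: observed pre trips, same scenario.

    Excess = total_post − counterfactual_post, exactly conserving.
    """
    window = series.window
    organ = series.organ

    post_months = pd.PeriodIndex(
        pd.to_datetime(trips_post["transplant_date"]), freq="M"
    )
    m_index = np.array([(p - window.start_month).n + 1 for p in post_months])
    tab = series.table
    observed_mean = tab["mean_distance"]
    predicted = fit.intercept + fit.pre_slope * tab.index.to_numpy(dtype=float)
    obs_m = observed_mean.reindex(m_index).to_numpy(dtype=float)
    if np.any(~np.isfinite(obs_m)) or np.any(obs_m == 0):
        raise ValueError("post month with zero/undefined observed mean: rescale undefined")
    pred_m = pd.Series(predicted, index=tab.index).reindex(m_index).to_numpy(dtype=float)

    post_dist = trips_post["distance_miles"].to_numpy(dtype=float)
    scaled_dist = post_dist * (pred_m / obs_m)
    scaled_dist = np.maximum(scaled_dist, 0.0)

    total_post = _fleet_emissions(post_dist, organ, scenario, factors)
    if reassign_modes:
        counterfactual_post = _fleet_emissions(scaled_dist, organ, scenario, factors)
    else:
        observed_mode_factors = _mode_factors(post_dist, organ, scenario, factors)
        counterfactual_post = float(np.sum(scaled_dist * observed_mode_factors))
    pre = _fleet_emissions(
        trips_pre["distance_miles"].to_numpy(dtype=float), organ, scenario, factors
    )
    return ScenarioEmissions(
        organ=organ,
        threshold=scenario.threshold,
        total_post_emissions=total_post,
        counterfactual_post_emissions=counterfactual_post,
        pre_emissions=pre,
        n_post_transplants=len(trips_post),
    )


def scenario_grid(
    trips_post: pd.DataFrame,
    series: MonthlySeries,
    fit: ITSFit,
    factors: EmissionFactors,
    trips_pre: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    reassign_modes: bool = False,
) -> dict[float, ScenarioEmissions]:
    """Run :func:`excess_emissions` for one organ across all thresholds."""
    return {
        thr: excess_emissions(
            trips_post,
            series,
            fit,
            ModeScenario(threshold=thr),
            factors,
            trips_pre,
            reassign_modes=reassign_modes,
        )
        for thr in thresholds
    }


def grid_to_frame(grids: dict[str, dict[float, ScenarioEmissions]]) -> pd.DataFrame:
    """Excess-emission table: rows = thresholds, columns = organs."""
    thresholds = sorted({t for g in grids.values() for t in g})
    return pd.DataFrame(
        {
            organ: [grids[organ][t].excess_emissions for t in thresholds]
            for organ in grids
        },
        index=pd.Index(thresholds, name="threshold"),
    )


def compose_bounds(grid: pd.DataFrame) -> dict[str, float]:
    """Most-liberal / most-conservative all-organ excess-emission totals.

    ``grid`` holds excess kg CO2e with thresholds as rows and organs as
    columns. The liberal composition takes the *lowest* threshold for
    charter organs (maximum flying, maximum charter emissions) and the
    *highest* threshold for kidney (commercial flights carry nothing, so
    more driving means more kidney emissions); the conservative
    composition is the reverse. Because each organ's excess is monotone
    in threshold, these bracket every mixed-threshold composition.
    """
    if grid.isna().any().any():
        raise ValueError("scenario grid has missing cells")
    lo, hi = grid.index.min(), grid.index.max()
    liberal = conservative = 0.0
    for organ in grid.columns:
        if organ in CHARTER_ORGANS:
            liberal += grid.loc[lo, organ]
            conservative += grid.loc[hi, organ]
        else:
            liberal += grid.loc[hi, organ]
            conservative += grid.loc[lo, organ]
    return {
        "most_liberal_total": float(liberal),
        "most_conservative_total": float(conservative),
    }


def proportion_under(
    trips: pd.DataFrame,
    cutoff: float,
    window: ObservationWindow,
    group_by: str | None = None,
) -> dict:
    """Fraction of trips strictly shorter than ``cutoff`` miles.

    Reported pre and post separately, overall and (optionally) per group
    (e.g., region). Empty groups are reported as None, not 0.
    """
    pre, post, _ = _split_pre_post(trips, window)

    def _prop(frame: pd.DataFrame):
        if len(frame) == 0:
            return None
        return float((frame["distance_miles"] < cutoff).mean())

    out: dict = {}
    for name, frame in (("pre", pre), ("post", post)):
        entry = {"overall": _prop(frame)}
        if group_by is not None:
            groups = sorted(trips[group_by].dropna().unique())
            entry["by_group"] = {g: _prop(frame[frame[group_by] == g]) for g in groups}
        out[name] = entry
    return out
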