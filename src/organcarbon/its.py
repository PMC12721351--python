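"""Interrupted time series on monthly mean trip distance.

The policy evaluation treats each organ's acuity-circle implementation
date as a known interruption and fits a segmented ordinary-least-squares
regression to the monthly mean distance travelled per organ:

    E[y_m] = alpha + beta1 * m + beta2 * post_m + beta3 * post_m * e_m

where m = 1..T indexes window months, post_m indicates the post period
(the implementation month onwards), and e_m is months elapsed since the
implementation month (0 in that month). beta2 is the immediate level
change at implementation, beta3 the slope change, and beta1 + beta3 the
post-segment slope.

The counterfactual for each post month extrapolates the pre-policy trend
(alpha + beta1 * m); excess miles are the observed-minus-counterfactual
mean differences scaled by monthly procurement counts and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ObservationWindow


@dataclass
class MonthlySeries:
    """Per-calendar-month mean distance and procurement count.

    ``table`` is indexed by the 1-based window month m and carries
    columns month (Period), mean_distance (NaN when empty),
    n_procurements, is_post, elapsed_post.
    """

    organ: str
    window: ObservationWindow
    table: pd.DataFrame

    @property
    def n_months(self) -> int:
        return len(self.table)

    def nonempty(self) -> pd.DataFrame:
        return self.table[self.table["n_procurements"] > 0]


def aggregate_monthly(trips: pd.DataFrame, window: ObservationWindow) -> MonthlySeries:
    """Collapse resolved trips to the per-month mean-distance series.

    Every calendar month of the window appears in the output; months with
    no procurements carry NaN mean and count 0 (they are excluded from
    the regression but retained for excess accounting).
    """
    if len(trips) == 0:
        raise ValueError("no trips to aggregate")
    months = window.months
    dates = pd.PeriodIndex(pd.to_datetime(trips["transplant_date"]), freq="M")
    grouped = trips.groupby(dates)["distance_miles"]
    means = grouped.mean().reindex(months)
    counts = grouped.size().reindex(months, fill_value=0).astype(int)
    m = np.arange(1, len(months) + 1)
    impl_idx = window.n_pre_months + 1
    table = pd.DataFrame(
        {
            "month": months,
            "mean_distance": means.to_numpy(),
            "n_procurements": counts.to_numpy(),
            "is_post": m >= impl_idx,
            "elapsed_post": np.maximum(m - impl_idx, 0),
        },
        index=pd.Index(m, name="m"),
    )
    if int(table["n_procurements"].sum()) == 0:
        raise ValueError("entirely empty monthly series")
    return MonthlySeries(organ=window.organ, window=window, table=table)


def series_from_table(organ: str, window: ObservationWindow, means, counts) -> MonthlySeries:
    """Build a MonthlySeries directly from per-month means and counts
    (mainly for tests and closed-form checks)."""
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=int)
    months = window.months
    if not len(means) == len(counts) == len(months):
        raise ValueError("means/counts length must equal window months")
    m = np.arange(1, len(months) + 1)
    impl_idx = window.n_pre_months + 1
    table = pd.DataFrame(
        {
            "month": months,
            "mean_distance": means,
            "n_procurements": counts,
            "is_post": m >= impl_idx,
            "elapsed_post": np.maximum(m - impl_idx, 0),
        },
        index=pd.Index(m, name="m"),
    )
    return MonthlySeries(organ=organ, window=window, table=table)


@dataclass(frozen=True)
class ITSFit:
    """Segmented-regression coefficients for one organ window."""

    intercept: float
    pre_slope: float
    level_change: float
    slope_change: float
    p_pre_slope: float
    p_level: float
    p_slope_change: float
    residual_variance: float
    n_obs: int

    @property
    def post_slope(self) -> float:
        return self.pre_slope + self.slope_change

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "pre_slope": self.pre_slope,
            "level_change": self.level_change,
            "slope_change": self.slope_change,
            "post_slope": self.post_slope,
            "p_pre_slope": self.p_pre_slope,
            "p_level": self.p_level,
            "p_slope_change": self.p_slope_change,
            "residual_variance": self.residual_variance,
            "n_obs": self.n_obs,
        }


def fit_its(series: MonthlySeries, weighted: bool = False, robust: bool = False) -> ITSFit:
    """Fit the segmented regression to a monthly series.

    Unweighted OLS on the monthly means by default (each month is one
    observation regardless of volume); ``weighted=True`` weights months
    by procurement count. ``robust=True`` switches the coefficient
    covariance to heteroskedasticity/autocorrelation-robust (HAC,
    Newey-West), affecting p-values only. Empty months are dropped.

    Raises ``ValueError`` when either segment has fewer than 2 non-empty
    months (the design would be rank deficient).
    """
    obs = series.nonempty()
    n_pre = int((~obs["is_post"]).sum())
    n_post = int(obs["is_post"].sum())
    if n_pre < 2 or n_post < 2:
        raise ValueError(
            f"need >= 2 non-empty months per segment (got {n_pre} pre, {n_post} post)"
        )
    m = obs.index.to_numpy(dtype=float)
    post = obs["is_post"].to_numpy(dtype=float)
    elapsed = obs["elapsed_post"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(m), m, post, post * elapsed])
    y = obs["mean_distance"].to_numpy(dtype=float)
    if weighted:
        model = sm.WLS(y, X, weights=obs["n_procurements"].to_numpy(dtype=float))
    else:
        model = sm.OLS(y, X)
    if robust:
        maxlags = max(1, int(np.floor(4 * (len(y) / 100.0) ** (2.0 / 9.0))))
        res = model.fit(cov_type="HAC", cov_kwds={"maxlags": maxlags})
    else:
        res = model.fit()
    return ITSFit(
        intercept=float(res.params[0]),
        pre_slope=float(res.params[1]),
        level_change=float(res.params[2]),
        slope_change=float(res.params[3]),
        p_pre_slope=float(res.pvalues[1]),
        p_level=float(res.pvalues[2]),
        p_slope_change=float(res.pvalues[3]),
        residual_variance=float(res.scale),
        n_obs=int(res.nobs),
    )


@dataclass
class ExcessResult:
    """Counterfactual excess miles over the post period.

    ``table`` covers the post months with columns month, observed_mean,
    predicted_mean (pre-trend extrapolation), delta, n_procurements and
    excess_miles = delta * n; empty months contribute 0.
    """

    organ: str
    table: pd.DataFrame
    total_excess_miles: float

    @property
    def n_post_transplants(self) -> int:
        return int(self.table["n_procurements"].sum())


def counterfactual_excess(series: MonthlySeries, fit: ITSFit) -> ExcessResult:
    """Excess miles attributable to the policy, by pre-trend extrapolation.

    For each post month the counterfactual mean is alpha + beta1 * m (no
    level- or slope-change terms); the delta to the observed mean is
    multiplied by that month's procurement count and summed over the post
    period.
    """
    post = series.table[series.table["is_post"]].copy()
    m = post.index.to_numpy(dtype=float)
    post["predicted_mean"] = fit.intercept + fit.pre_slope * m
    post["observed_mean"] = post["mean_distance"]
    post["delta"] = post["observed_mean"] - post["predicted_mean"]
    post["excess_miles"] = post["delta"].fillna(0.0) * post["n_procurements"]
    table = post[
        ["month", "observed_mean", "predicted_mean", "delta", "n_procurements", "excess_miles"]
    ]
    return ExcessResult(
        organ=series.organ,
        table=table,
        total_excess_miles=float(table["excess_miles"].sum()),
    )


def plot_its(series: MonthlySeries, fit: ITSFit, ax=None):
    """Observed monthly means with fitted segments and the counterfactual
    pre-trend extrapolation (dashed), one panel per organ."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    tab = series.table
    m = tab.index.to_numpy(dtype=float)
    ax.scatter(m, tab["mean_distance"], s=10, color="0.4", label="observed monthly mean")
    pre = ~tab["is_post"].to_numpy()
    fitted = (
        fit.intercept
        + fit.pre_slope * m
        + fit.level_change * tab["is_post"].to_numpy(dtype=float)
        + fit.slope_change * tab["elapsed_post"].to_numpy(dtype=float)
    )
    ax.plot(m[pre], fitted[pre], color="C0", label="fitted pre trend")
    ax.plot(m[~pre], fitted[~pre], color="C1", label="fitted post trend")
    ax.plot(
        m[~pre],
        fit.intercept + fit.pre_slope * m[~pre],
        color="C0",
        linestyle="--",
        label="counterfactual (pre trend)",
    )
    impl = series.window.n_pre_months + 1
    ax.axvline(impl - 0.5, color="k", linewidth=0.8, alpha=0.6)
    ax.set_xlabel("window month")
    ax.set_ylabel("mean distance (miles)")
    ax.set_title(series.organ)
    ax.legend(fontsize=8)
    return ax
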