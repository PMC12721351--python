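# Methods

## Observation windows

Each organ's window is materialized as whole calendar months. Writing
`d` for the number of months from the implementation month to the
end-of-data month (2023-11), the window starts `d` months before the
implementation month, so the implementation month sits at the exact
center of a `2d+1`-month span and is the same month-distance from both
ends. With the shipped policy calendar this yields lung Nov 2011–Nov
2023, heart Sep 2013–Nov 2023, liver May 2016–Nov 2023 and kidney
Jul 2018–Nov 2023. The implementation month belongs to the post period
(`elapsed_post = 0` there; a transplant dated on the implementation day
is post), so `n_post_months = n_pre_months + 1` — the odd middle month
is the price of a symmetric whole-month window. Months are calendar
months, not 30-day blocks; this is the convention that reproduces all
four window starts above.

Cohort filters run in a fixed order — living donor, then missing center
ID, then window membership — and tally the first matching reason, so
kept + tallied always equals the input count. Endpoint-resolution
failures (no ZIP and no city-state match) drop the record with a
logged count rather than aborting the run, matching how registry
analyses treat a handful of bad addresses.

## Distance model

Distances are great-circle miles on a sphere of radius 3958.8 mi (mean
Earth radius; configurable) via the haversine formula, between ZIP-code
centroids supplied as an input gazetteer. No road routing is attempted.
When the recipient ZIP is missing, the center's "City, ST" centroid is
used and the trip is flagged `city_state_fallback`.

## Interrupted time series

The segmented regression is unweighted OLS of monthly mean distance on
`{1, m, post, post × elapsed_post}`; each non-empty month is one
observation regardless of volume (a count-weighted fit is available via
`weighted=True`). The time origin puts `m = 1` at the window start and
`elapsed_post = 0` in the implementation month, so the level-change
coefficient is the jump at the start of the post segment. No
autocorrelation structure is modeled; `robust=True` switches to HAC
(Newey–West) standard errors, which changes p-values only. Months with
zero procurements are dropped from the fit but kept in the excess table
with zero contribution. A fit requires at least two non-empty months in
each segment.

The fit reports the pre slope β₁, the slope change β₃, and the
post-segment slope β₁+β₃ separately. Published post-policy trend
estimates are interpreted as post-segment slopes; for liver the
published figure is ambiguous between a slope change and a post slope,
so the generator default adopts the post-slope reading and no liver
post-slope recovery is asserted.

Counterfactual excess for a post month is
`(observed mean − (α + β₁·m)) × n_procurements`, summed over the post
period. For a noise-free cohort with level change Δ and slope change γ
this closed-forms to `Σ_m n_m (Δ + γ·e_m)`, which the end-to-end tests
check exactly.

## Emission accounting

Per-mile factors (kg CO2e/mile) are inputs with defaults: drive 0.448
(large petrol car, ≈0.278 kg/km, UK DESNZ 2023 vintage), charter 2.06
(whole-aircraft short-haul light-jet basis; the two travellers /
~200 kg payload enter through this aircraft-level attribution, not a
per-passenger share), commercial exactly 0 (the organ rides a flight
that would operate anyway). Absolute emission totals are only as good
as these factors; the analysis's comparative structure (scenario
directions, bounds, percent increases) does not depend on their exact
values.

Mode imputation is strict: a trip flies iff its distance exceeds the
scenario threshold; ties drive. The counterfactual post fleet rescales
every observed post trip by its month's (counterfactual mean / observed
mean) ratio. **Each trip keeps the mode imputed at its observed
distance.** The alternative — re-imputing modes at the rescaled
distance — is available (`reassign_modes=True`) but is not the default,
because it systematically inflates excess at higher thresholds: a
shortened counterfactual trip that drops below the threshold gets
billed at the cheap drive rate while its observed twin still pays
charter, so the excess *grows* as the threshold rises, inverting the
scenario table's expected direction. With modes held fixed, excess
emissions are exactly the per-mode carbon intensity applied to the
excess miles, and charter-organ excess is non-increasing (kidney's
non-decreasing) in the threshold on any cohort whose post months sit
above the counterfactual trend. Excess + counterfactual = observed
total exactly, by construction.

The most-liberal all-organ composition takes the lowest threshold for
charter organs and the highest for kidney; most-conservative is the
reverse. Monotonicity per organ class makes these totals bracket all
5⁴ mixed-threshold compositions, which the tests verify exhaustively on
a toy grid.

## Synthetic cohort generator

The generator emulates a registry extract: one record per organ
movement with donor/recipient pseudo-ZIPs (organ-prefixed synthetic
codes registered in an emitted gazetteer), transplant dates spread
uniformly within each month (implementation-month dates start at the
implementation day), a living-donor fraction, missing center IDs, and
missing recipient ZIPs that fall back to a resolvable "City, ST" entry
(or, optionally, to nothing, to exercise the error path).

Monthly target means follow the segmented model; per-trip distances are
gamma with that mean and shape `1/trip_noise²` (CV = `trip_noise`,
degenerate at the target when 0). Gamma is a stand-in: the published
analysis reports only monthly means, never a trip-level distance
distribution, so any strictly positive right-skewed family with a
controllable mean would serve. Coordinates are placed by drawing the
recipient uniformly over a continental-US-like box (25–49°N,
67–124°W) and back-projecting the donor along a uniform random bearing
at the drawn distance, so the gazetteer centroids reproduce each drawn
distance to floating-point accuracy. Specs whose target trend crosses
zero inside the window are rejected.

Default study conditions per organ: the published implementation dates;
monthly volumes equal to the published cohort sizes divided by window
months (lung 196, heart 288, liver 705, kidney 1519); baselines chosen
so the pre-window average of the trend equals the published pre-policy
mean (lung 245, heart 212, liver 189, kidney 251 mi); pre slopes
(−0.39, −0.54, −0.24, −1.72 mi/month), level changes (−31, +104, +57,
+14 mi) and post slopes (3.40, 1.56, 0.34, 2.71 mi/month) equal to the
published estimates; living-donor fraction 0.14 and missing-center-ID
fraction 0.002 (the published exclusion counts relative to the total
extract); missing-ZIP fraction 5×10⁻⁵; trip noise CV 0.9 as a
realistic right-skew for trip distances.

What the generator does **not** emulate: geographic clustering of
centers and donors (endpoints are uniform in a box), seasonality, the
COVID-19 disruption, donation-after-circulatory-death growth, machine
perfusion, regional allocation structure beyond a random region label,
or any waitlist/offer dynamics. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the segmented-model data
generating process, not that the published national estimates are
externally valid.

## Problem sizes and numerical choices

Tests and the acceptance script scale volumes down (typically 4–50
records/month, and a 25-month window for the Monte-Carlo calibration)
since recovery at zero noise is exact at any volume and the Monte-Carlo
check needs replicates, not volume; the Monte-Carlo suite uses 200
replicates at 50 procurements/month with CV 0.5 noise and accepts mean
bias of the level-change estimator within 3 Monte-Carlo standard
errors of zero. OLS is delegated to statsmodels and cross-checked
against an explicit normal-equations solve to 1e−8; haversine is
cross-checked against an independent great-circle implementation to
0.01%. The haversine argument is clamped to [0, 1] before `asin` to
guard antipodal rounding. Percent increases use the pre-period observed
emissions under the same scenario as denominator; emission tables round
to 2 decimals (miles to whole numbers, percentages to one decimal) in
human-readable outputs while JSON artifacts keep full precision.

## Known limitations

Straight-line distance understates true travel; team travel to the
donor hospital, recovery-facility legs, couriers and dry runs are not
counted, so emission totals are lower bounds in that respect. The
charter factor treats all charter flights as one aircraft class.
Commercial-flight attribution of zero is an assumption, not a
measurement. The ITS assumes a single known interruption and linear
segments; no seasonal terms or changepoint detection.
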