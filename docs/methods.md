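# Methods

## Problem and model

A pixel that converts from vegetated land to an open water surface (a waste
lagoon) shows an abrupt, persistent drop in near-infrared surface
reflectance. We model the cleaned per-pixel series as piecewise-normal with
at most one changepoint and estimate the split by minimising the summed
segment cost over all admissible splits — the at-most-one-change (AMOC)
search, which is exactly what binary segmentation reduces to when
constrained to a single changepoint. We implement the single-split argmin
directly rather than as a recursive segmentation: the result is identical
and the scan is exactly testable against an exhaustive re-scan.

Two cost metrics are supported. The change-in-mean cost of a segment is its
residual sum of squares about the segment mean (normal likelihood with
common variance, up to constants). The change-in-mean-and-variance cost is
`n_k · ln(max(σ̂²_k, ε))` with the maximum-likelihood segment variance and a
floor `ε = 1e-8` (squared scaled-reflectance units) guarding `ln 0` on
numerically flat segments; a fit whose floor engages is flagged degenerate.
No penalty term is used — the model space is fixed at one changepoint, so
there is no model-selection step. Ties in the scan break toward the smallest
split index. A fit whose segment means differ by less than a configurable
floor (default 1e-6) is flagged degenerate (no meaningful change).
Change-in-mean is the default; the mean-and-variance variant is retained
behind a switch because it adds no accuracy in practice and is more fragile
on low-variance segments. Normality is assumed, not enforced; the scan is a
least-squares criterion and degrades gracefully for skewed series.

## Decision rules

The changepoint is attributed to the **first post-change observation** (the
first image showing water); construction year = calendar year of that
observation. The alternative convention (last pre-change image) differs by
at most one acquisition interval (~16 days), which the ±1-year validation
tolerance absorbs. Three rules partition every fit:

1. changepoint year ≤ `era_start` → PRE_ERA (the record cannot date
   conversions at or before its first usable years);
2. post-segment mean above pre-segment mean → PRE_ERA (a rising step is not
   a land-to-water conversion, so the conversion predates the record);
3. otherwise YEAR = changepoint year; years past `era_end` are reported with
   an out-of-window flag rather than suppressed, since no principled
   reassignment exists.

`era_start`/`era_end` default to 1986/2010, the interior of a 1984–2012
image record (a conversion needs imagery both before and after it); both
are configurable for other sensors or records.

Validation: a YEAR estimate is correct within ±`tolerance_years` (default
1) of the observed year; a PRE_ERA estimate is correct when the observation
is at or before `era_start`. When the observation itself is pre-era, YEAR
estimates within the tolerance of `era_start` are also credited — the
symmetric reading of the tolerance at the era boundary; the scorecard's
`notes` field states the rule applied so the choice is visible in every
report. Accuracy is non-decreasing in the tolerance by construction.

## Cleaning

Scaled surface reflectance above 10,000 is physically impossible for land
or water and indicates bright contamination (cloud); those observations are
removed first, with a strict inequality so exactly the contaminated values
go. Smoothing is a centred moving average over observation index (default
window 3, truncated at the series ends), chosen as the simplest linear
smoother; `window=1` disables it. Removal precedes smoothing so a
contaminated value is never smeared into its neighbours. No gap
interpolation is performed: the changepoint scan is defined on the
irregular observation index, and the date attribution uses the real
calendar dates.

## Synthetic data

The generator emulates a Landsat-5-like band-4 record: observations every
16 days from 1984-01-01 to 2012-12-31 (~662 acquisitions), each
independently censored with probability 0.2 (cloud cover), values
`pre_mean = 3500` before the change date and `post_mean = 800` on/after it
(vegetated vs water NIR levels on the 0–10,000 scale), Gaussian noise with
sd 300, and with probability 0.01 a bright outlier drawn uniformly from
(10,000, 20,000]. Outliers are strictly above 10,000 so the cleaning rule
removes exactly the injected set — making the cleaning stage testable by
count. An optional commissioning-era artifact replaces the level of **all**
observations dated in 1984 with `artifact_mean` (default 6000): we treat
the artifact as a sensor effect, so it overrides the ground state; its
magnitude is a free parameter because no measured value exists.

What the generator does not emulate: radiative-transfer realism, seasonal
phenology, multi-band structure, gradual construction (the step is
instantaneous), lagoon decommissioning or expansion, and spatially
correlated cloud cover. Passing recovery tests on this generator therefore
demonstrates that the algorithm recovers the model it assumes under
realistic noise, cadence and censoring — not that it reaches any particular
accuracy on real imagery, where those unmodelled effects are the dominant
error sources.

Validation cohorts draw construction years uniformly over a configurable
range with the construction day uniform within the year; per-site seeds
derive deterministically from the cohort seed. Landscapes place sites
uniformly in a lon/lat box and generate water features (rectangles and
polylines) with classes from {reservoir, canal/ditch, lake/pond,
stream/river, estuary, swamp/marsh}.

## Spatial stage

Polygon hydrography features with geodesic area < 0.05 km² are removed
before distance analysis (small polygons are disproportionately
misclassified); polylines carry no area and are always retained — an
interpretation, since an area filter cannot apply to them. Known
misclassified features can be excluded by id upstream of the filter.

Nearest distances are geodesic on the WGS84 ellipsoid. The point-to-point
primitive is Vincenty's inverse method (agrees with independent
implementations to sub-millimetre at these scales; a spherical fallback
covers the antipodal non-convergence case, which cannot arise here).
Feature boundaries are densified to ≤ 0.001° per segment (~100 m) and the
minimum over vertices is refined by golden-section search along the
segments adjacent to the best vertex, keeping the point-to-boundary error
far below 1 m; halving the densification step moves test-fixture distances
by well under 1 m. A site inside a polygon feature is at distance 0.

Polygon areas (for the area filter and watershed densities) use the
spherical-excess line integral evaluated in authalic latitude on densified
rings — an equal-area mapping of the ellipsoid, accurate to far better than
the 1% that any density or filtering decision here could notice. Density
per polygon is `count / area_km2 × 100` with point-in-polygon on lon/lat; a
site on a shared boundary counts toward the first covering polygon in
stable id order, and sites covered by no polygon are reported separately.

Cohort summaries report mean and median nearest distance per construction
cohort (default bins: <1987 including PRE_ERA, 1987–89, 1990–91, 1992–93,
1994–95, 1996–97, ≥1998) overall and per feature class; empty cells are
absent rather than zero. The summary conserves records: cohort counts sum
to the number of input records.

The Mann–Kendall test uses S = Σ_{i<j} sign(x_j − x_i), the tie-corrected
variance [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18, the ±1 continuity
correction in Z, and a two-sided normal p-value; τ is Kendall's rank
correlation with time (tie-corrected denominator). An all-tied series is
flagged degenerate with S = 0 and no trend. Against the exact permutation
null for distinct-valued series, the normal approximation's worst-case
p-value discrepancy is 0.0252 at n = 4, shrinking to 0.0123 at n = 8; tests
assert a 0.03 envelope. Trend analysis is intended for the annual median
distances (one value per estimated construction year), but the operation is
generic over any ordered series.

## Numerical and design choices

- The production scan uses prefix sums (O(n)); variances are clipped at 0
  against catastrophic cancellation. Tests assert exact argmin agreement
  with an exhaustive from-scratch re-scan over random series.
- Dates are ISO-8601 calendar dates everywhere; decimal years exist only as
  a plotting helper.
- All randomness in a run flows from one seed; derived seeds stay below
  2³¹.
- Problem sizes in the test and acceptance runs (1,000 oracle series of
  n ≤ 60; 500-site recovery cohorts; 200 pre-era replicates) were chosen to
  give binomial standard errors of about 1 percentage point on the reported
  rates while keeping the whole suite interactive.

## Limitations

- One changepoint only: decommissioning, expansion, or multiple land-use
  transitions are out of scope and will bias the estimate when present.
- The estimator cannot date conversions at or before `era_start`; it only
  classes them PRE_ERA.
- Real-imagery effects (partial-pixel lagoons, snow, sensor drift,
  within-year cloud seasonality) are not simulated; accuracy numbers from
  synthetic cohorts are upper bounds on real-data performance.
- GeoJSON in WGS84 is the only geometry interchange format; users export
  national hydrography/watershed products to GeoJSON themselves.
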