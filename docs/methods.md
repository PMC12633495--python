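# Methods

## Smoke-day geometry

All area arithmetic runs in a spherical Lambert azimuthal equal-area
projection anchored at the study-area centroid (Earth radius 6371.0088 km,
output in km). The projection preserves spherical areas exactly, so km²
overlaps are projection-independent up to the spherical-Earth approximation
(< 0.3% vs an ellipsoid at this latitude and scale, well inside the 1%
tolerance used for the catchment total).

Per day, plume polygons are unioned before intersecting the study area:
"overlapped area" is a coverage quantity, and two overlapping plumes must
not be double-counted. Whether same-day plumes should be unioned at all is
an open convention; union is this package's decision. The 1 km² smoke-day
threshold is boundary-inclusive ("at least"). Invalid polygons (slivers,
bow-ties, as in operational plume feeds) are repaired by zero-buffer;
unrepairable geometry is a hard error naming the feature.

The shipped default study area is a synthetic stand-in for the four-county
greater-Albuquerque catchment: an irregular octagon centred near
(−106.6°, 34.9°), scaled so its equal-area total is 18,719 km². Only the
total area and rough location are emulated; county boundaries are not
redistributable here.

## Deviation attribution

Smoke PM₂.₅ (and identically BC) on a smoke day is observed value minus the
median of non-smoke-day values in the same calendar month pooled over the
year before, the index year and the year after, truncated at zero. Design
points the method statement leaves open, resolved as follows:

* "Same month" is calendrical (all Junes of y−1..y+1), not a rolling ±30-day
  window.
* Smoke days never enter the baseline pool, including the index day's
  month-mates in other years.
* A month with no qualifying non-smoke day across all three years falls back
  (configurable) to pooling the two adjacent calendar months (`widen`,
  default) or to a missing baseline (`missing`). At the boundary of the
  record, missing neighbour years are dropped from the pool with a warning.
* Even-count medians are the mean of the middle pair.
* Missing cell-days propagate as NaN; they are never silently zeroed.

Region-level attribution operates on the area-mean daily series of the
member cells (equal 1 km² cells, so the unweighted mean; a weighted variant
is provided). Per-cell attribution then averaging is also available, and
the two agree exactly on spatially constant fields.

## Exposure windows

Windows are the X ∈ {7, 15, 30, 60} consecutive days ending the day before
the visit: the questionnaires describe the preceding weeks, and whether the
visit day itself counts is not determined by the study description — its
exclusion is this package's convention. Window means divide by X (non-smoke
days contribute zero), not by the number of smoke days; the cumulative
overlapped area is the plain day-by-day sum with no spatial de-duplication,
which is why it can exceed the catchment's size over long windows.
Residence-level assignment maps a point to the nearest 1 km cell center
(ties to the lowest cell id) in a local tangent plane.

## HRQoL scoring

SGRQ scores are 100 × (endorsed weight sum)/(maximum weight sum) per domain,
with the total pooling all domains. The official weights are licensed, so
they are configuration input; missing items are dropped from both sums up
to a cap (default 25% of the domain's total weight), beyond which the score
is missing. SF-36 uses the public-domain scoring: each item recoded to
0–100 (reverse-keyed items handled), then the per-domain mean of answered
items.

The two-factor reduction is confirmatory with a fixed simple structure
(physical: physical functioning, role physical, bodily pain, general
health; mental: mental health, role emotional, social functioning,
vitality), estimated by maximum likelihood on the correlation matrix of the
standardized domains (L-BFGS-B on the normal-theory discrepancy,
uniquenesses floored at 1e-3 with Heywood flagging, factor correlation free
via a tanh link). Factor scores use the regression method and are
re-standardized to mean 0, SD 1 on the fitting sample. The extraction
method and whether the factors correlate are documented defaults, not
established facts about the original analysis.

## Association models

OLS via statsmodels with the stated adjustment sets; binary covariates are
0/1 indicators, continuous covariates untransformed. Unit scalings are pure
reparameterizations (β per 0.05 μg/m³ = 0.05 × β per 1 μg/m³ exactly;
per-IQR uses the analysis sample's IQR and errors if it is zero). No
multiple-testing correction: nominal P values are reported and evidence is
weighed across metrics and windows. Interactions add a modifier × exposure
product (modifier binary, both strata required) and flag P < 0.1; they are
run on 7-day metrics by default, where associations are strongest. Winter
for the sensitivity exclusion defaults to December–February (configurable;
"winter" has no canonical definition here). Rank-deficient designs error
with the collinear columns named.

## Synthetic generator

What it emulates, and the defaults that define the study conditions:

* **Calendar**: per-day Bernoulli smoke indicators with monthly
  probabilities peaking in the fire season (Jun 0.32, Jul 0.28, May/Aug
  0.20, winter 0.01), giving ≈480 smoke days per 4383-day (12-year) record,
  the scale of the motivating study's 474/3909 split. Each smoke day gets a
  plume disk guaranteed to overlap the catchment by ≥ 1 km²; 10% of
  non-smoke days get decoy plumes far outside it.
* **Fields**: per-cell-day concentration = lognormal baseline + additive
  smoke elevation on smoke days. Baseline medians are calibrated so the
  non-smoke-day *mean* is 4.14 μg/m³ PM₂.₅ / 0.16 μg/m³ BC given the default
  noise (σ_log = 0.5, a realistic day-to-day GSD of ≈1.6): median = mean ·
  exp(−σ²/2). Daily regional elevations are exponential with mean
  2.41 μg/m³ PM₂.₅ (= 6.55 − 4.14) and BC tied by the elevation ratio
  0.09/2.41; a lognormal per-cell factor (SD 0.15, mean 1) supplies
  within-region spatial variation, which no published figure constrains —
  it is a parameter, not an assertion. The planted additive term and
  baseline draw are stored per cell-day, so total − planted = baseline is
  checkable exactly.
* **Cohort**: n = 747 with the study's covariate marginals (mean age 56.9,
  51.27% female, 24.77% Hispanic, 64.12% some college, 59.84% current
  smokers, pack-years 41.4 ± 21, 32.26% ever-woodsmoke, 30.66% CMH).
  Airway-obstruction and comorbidity prevalences are not tabulated in the
  source description; 0.35 and 0.50 are typical for a ≥10-pack-year smoker
  cohort. Visit dates are uniform over the interior of the record (one year
  + 60 days trimmed at the start, one year at the end) so every visit has
  full window coverage and fully pooled baselines.
* **Outcomes**: outcome = intercept + covariate effects + Σ planted β ×
  exposure metric + Gaussian noise. Default planted effects are the 7-day
  smoke-PM₂.₅ coefficients used as recovery targets (SGRQ
  activity/impacts/symptom/total 5.51/3.27/6.15/4.68 points per μg/m³;
  SF-36 physical/mental −0.214/−0.172 SD per μg/m³). Noise SDs (SGRQ 14–24
  points, factors ≈0.9 SD) are realistic residual scales for these
  instruments. SGRQ scores are clamped to [0, 100] with clamp counting and
  a warning above 5%; intercepts sit mid-range (28–48) so clamping stays
  ≈1–2%, because boundary censoring attenuates planted slopes by roughly
  the clamped fraction — a design constraint of any recovery experiment on
  a bounded score. SF-36 factor outcomes are generated directly on the
  standardized factor scale (unclamped); routing them through item scoring
  and factor extraction would rescale the planted coefficient by the
  extraction shrinkage, so the factor model is validated separately by
  parameter-recovery simulation instead.

What the generator does **not** emulate: spatial correlation of the
baseline field beyond per-cell independence, realistic plume morphology,
exposure measurement error relative to the truth the outcomes are generated
from, repeated visits, and confounding (covariates are independent of
exposure, so adjusted and crude effects coincide in expectation). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated conditions, not robustness to confounding or
exposure error in real data.

## Problem sizes and numerics

The validation experiments use one fixed environmental record (6-year
default range, ≤ 9 cells for the regional series) with 500 replicated
cohorts of n = 747 for coefficient recovery, and a 12-year record at the
474/3909-day scale for the air-quality calibration; these sizes put
Monte-Carlo error well below the tolerances being checked while keeping a
full run around a minute. Attribution equality against the naive
double-loop oracle is exact (atol 1e-12); OLS against the normal-equations
solution is checked at 1e-8; the CFA optimizer runs L-BFGS-B with ftol
1e-12 and per-factor sign orientation (loadings oriented positive).
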