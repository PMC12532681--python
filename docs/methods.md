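# Methods

## The model

The package estimates smoothed temporal trends for stations that are
individually too sparsely observed to carry a trend.  Each station `l` gets
a locally weighted least-squares fit of the centered response on time,

    Y_l = β_l0 + β_l · t + ε_l,     ε_l ~ N(0, σ²),

over a window of nearby observation rows, where "nearby" is Euclidean
distance in a chosen coordinate system.  Three coordinate systems are
supported by one engine:

* **geographic** — projected easting/northing (classic GWR);
* **PCA scores** — the first components of the standardized station ×
  covariate table (unsupervised "thematic" coordinates);
* **PLS1 scores** — components extracted to maximize covariance with a
  per-station trend proxy (supervised thematic coordinates).

The window is adaptive: for a target point, the bandwidth `b` is the
distance to its k-th nearest observation row (self included), and weights
follow the bi-square kernel `(1 − (d/b)²)²` for `d < b`, zero beyond.
Observation **rows** define neighborhoods, not stations: a station's
repeated visits share its coordinates and always enter its own window at
distance zero, which is how long-format data behave in standard GWR
software.

## Pre-processing chain

Order of operations: reporting-limit substitution → log10 transform →
summaries.  Summaries on the log scale stabilize the skew of concentration
data, which is the point of transforming before (not after) computing
levels and changes.

* **Censoring.**  A value flagged below its reporting limit becomes half
  the limit.  Chloride's limit changed over the record, so all Cl values at
  or below the historical maximum limit are set to half that maximum,
  flagged or not — otherwise early low values would not be comparable.
  The operation is idempotent.
* **Station filtering.**  Stations need at least two response observations
  inside the trend window (2012–2023 by default); a configurable exclusion
  list handles known-bad stations (default empty — hard-coding station
  names would tie the package to one dataset).
* **Covariate table.**  One row per station, 36 covariates under the
  default schema, in three roles: 8 *change* (six log10-chemistry
  first/last annual changes + Theil–Sen slopes of annual temperature and
  precipitation over 2012–2020), 10 *initial* (all eight chemistry
  variables incl. pH and alkalinity as 2008–2013 means, falling back to the
  first later value observed before 2018, else missing; plus the 2008–2013
  climate means), and 18 *constant* (15 clr-transformed land-use shares,
  catchment area, elevation, and the 1990–2020 precipitation mean).
  Alkalinity and pH get initial levels only, no change covariates.
  The enumerable constants would total 19 if both overall climate means
  were kept; the default schema resolves the count to 18 by keeping the
  overall precipitation mean only, since the temperature initial-window
  mean already carries the long-term thermal gradient.  The schema is
  configuration data, not code — any other resolution is a YAML edit.
* **Multiple in-window values for an initial level** are averaged
  (arithmetic mean); with a six-year revisit more than one is rare.
* **clr zeros** are replaced multiplicatively with half the smallest
  positive part of that composition before closure — the standard
  compositional-zero treatment; configurable in `clr(zero_policy=...)`.
* **Response.**  pH observations inside the trend window are station-wise
  mean centered, so between-station level differences do not masquerade as
  trends.
* **Missing covariates** stay missing through table construction and
  standardization; the coordinates step resolves them (complete-case by
  default; mean-imputation — zero on the standardized scale — as the
  alternative).  Complete-case is the default because no imputation model
  is part of the method.

## Coordinates

PCA is computed by SVD of the standardized (mean 0, sample variance 1,
n−1 divisor) covariate matrix, equivalent to eigendecomposition of the
correlation matrix; explained percentages are eigenvalue/p × 100.  PLS1
uses the NIPALS recursion with deflation of both X and y; the goal
variable — the per-station annual pH change, (last − first)/(years
between) on the native pH scale — is standardized internally, and reported
response-variance shares are on that standardized scale.  Both models
apply a deterministic sign convention (largest-magnitude loading of each
component is positive) to remove eigenvector sign ambiguity across
platforms.

Raw scores, not variance-rescaled ones, serve as coordinates: component 1
legitimately spans a wider range than component 2, so distances weight the
dominant gradient more — the same geometry a score plot shows.

## Time coding and why it matters

Station-wise centering of the response removes each station's level but
leaves its points on a line whose intercept depends on the station's mean
visit year: for a station with true slope β visited in years t₁…t_m, the
centered values are β(t − t̄_station).  If time is coded against a single
global origin, windows that mix visit panels regress points with different
per-station intercepts on a common intercept, which *attenuates* the slope
(the between-station contribution to the slope is exactly zero after
centering).  The package therefore pairs the centered response with
station-centered time by default (`time_coding="station_mean"`, the
classical within transformation), making every local fit an exact weighted
average of within-station slopes — a zero-noise constant-slope scenario is
recovered exactly at any bandwidth.  Coding against the trend-window
midpoint (`"window_midpoint"`) is available for strict comparability with
software that uses calendar time, with the attenuation caveat documented
here.

## Bandwidth selection

Leave-one-out cross-validation over a grid of k values (default: 12
geometrically spaced between max(10, p + 2) and n).  For each k, every
held-out unit is predicted from a local fit at its own coordinates with the
unit removed, and raw held-out squared errors are summed; the trace is
recorded for audit.  Ties break to the smallest k (less smoothing at equal
error).  The default CV unit is the observation, matching standard GWR
practice; note that the response centering uses within-station information,
so observation-level CV carries a mild leakage — station-level
leave-out (`cv_unit="station"`) avoids it at extra cost.  An exhaustive
grid rather than golden-section search keeps selection deterministic.

Degenerate windows (fewer than two distinct positively weighted times)
yield NaN fits flagged `"degenerate"`; they never silently inflate the
bandwidth, and a k whose CV pass hits any degenerate window scores
infinity.

Numerical details: the local fit is solved in closed form from the weighted
sufficient statistics (vectorized over all targets); degeneracy is declared
when the weighted time variance falls below 1e-12 relative to its scale;
local R² = 1 − Σw(y−ŷ)²/Σw(y−ȳ_w)² is clipped to [0, 1] against rounding
and defined as 0 for a constant-response window.

## The synthetic generator

Two independent N(0,1) latent factors per station drive all observables:
L1 (latitude proxy: elevation +, temperature −, initial ionic chemistry −,
land-use composition tilted north/south) and L2 (common chemistry change:
the six ionic log10 change rates load positively on it).  The true pH
trend field defaults to

    β(L1, L2) = −0.03·expit(2·L2) + 0.01·expit(−L1²)

units/year, concentrating negative trends at positive L2 and a weak
positive bump at mid-range latitude.  pH observations are station mean +
β·(year − window midpoint) + N(0, 0.15²); 0.15 pH units reflects
between-visit autumn variability dominating laboratory precision.
Chemistry is log-normal (so the pipeline's log10 step recovers Gaussian
structure) with a common change component of ~0.012 log10/yr (≈ 3 %/yr,
the order of ionic-strength recovery trends) and 0.03 log10 units of
observation noise (~7 % on concentration); values below the per-variable
reporting limits are emitted as censored rows.  Land use is Dirichlet with
L1-dependent concentrations; climate series run 1990–2020 with a small
warming trend.  Stations draw a uniform panel offset, so with the default
6-year revisit and 2008–2023 span each station has 2–3 observations total
and exactly two inside 2012–2023 — the sparsest regime the method targets.
All randomness flows from one seed through a single generator; a
`merge_2018_panel` flag moves the 2018 panel to 2019 to emulate a lost
survey year.

What the generator does **not** emulate: spatial autocorrelation beyond
the latitude proxy, real geochemical covariance between different ions
beyond the two factors, seasonal or flow-driven variation, or non-Gaussian
outliers.  Passing recovery tests therefore show that the machinery
recovers structure *of the planted kind*; they do not certify performance
on survey data whose drivers are messier.

## Problem sizes and defaults

The recovery scenario runs 1000 stations (~2000 in-window response rows);
covariate assembly, PCA and the full CV grid complete in seconds.  The
bundled checks use 40–120-station surveys for structural properties and
the 1000-station scenario for recovery, where truth-versus-estimate
correlation is ≈ 0.87 with the CV-chosen k ≈ 300 interior to its grid.

## Known limitations

* No standard errors or hypothesis tests for local slopes.
* Single global bandwidth; no per-covariate (multiscale) bandwidths.
* Euclidean distances on raw scores only; no Mahalanobis option.
* PLS is single-response only; no robust/sparse PCA variants.
* The supervised (PLS) coordinate system uses a trend proxy built from two
  observations per station, so a single faulty measurement can displace a
  station far along the components; a generic station-exclusion list is the
  provided remedy.
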