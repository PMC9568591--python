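# Methods

## Pipeline overview

The package estimates a gridded ambient-population surface in four stages:

1. **Temporal averaging.** Daily LBS count rasters are averaged cell-wise
   over an inclusion calendar: whole months are opted in (default
   March–June and September–December, avoiding the Spring Festival window
   and school vacations) and individual public-holiday dates inside those
   months are opted out explicitly. The excluded dates are configuration,
   not code: which holidays contaminate a feed depends on the year and
   country. The mean is a running sum, so a year of national rasters never
   needs to be resident at once; when the stack is an in-memory sequence it
   is first ordered by date so the result is bit-invariant to input order.

2. **Zonal aggregation.** Each grid cell is assigned to the zone whose
   polygon covers the cell *center*; centers on shared boundaries go to the
   lowest zone index. Center containment (rather than area-weighted
   splitting) keeps every cell in exactly one county, which the conserving
   allocation of stage 4 requires. Zone anchors are polygon centroids
   (representative points when the centroid falls outside); when only a
   label raster is available the anchor is the mean of member cell centers,
   the raster analogue of the centroid.

3. **Regression.** The relation `ln pop = a · ln count + b` is fitted
   globally (OLS) and locally (GWR). Counties with zero aggregated count or
   zero population are excluded from the table — the log is undefined there
   — and logged with a reason; they re-enter at allocation time with a
   uniform fallback weight.

4. **Allocation.** Cell weights are `exp(b_i) · T_j^{a_i}` with each cell
   using its own county's coefficients (interpolated coefficient surfaces
   are deliberately out of scope); zero-count cells get zero weight and
   hence zero population — no background floor is added. County statistics
   are distributed proportionally, with a final renormalisation pass that
   pins each county sum to its statistic; all-zero-weight counties fall
   back to a uniform spread and are flagged in the diagnostics table.

## GWR details

* **Kernels.** Gaussian `exp(-½(d/h)²)` and bisquare `(1-(d/h)²)²·1{d<h}`.
  Distances are great-circle kilometres (haversine, R = 6371.0088 km)
  between anchors; degrees would distort with latitude over a
  continental extent.
* **Bandwidth.** Fixed (a radius in km) or adaptive (the distance to the
  k-th nearest county at each anchor, the anchor itself counted at rank 1).
  The default is adaptive bisquare with AICc selection — the common default
  of desktop GWR tools; fixed-Gaussian and leave-one-out CV are available
  through the configuration. Automatic selection uses golden-section search
  on log-bandwidth (fixed) or integer ternary search (adaptive); ties break
  toward the larger, smoother bandwidth. A local system with fewer than
  three effectively nonzero weights raises an error that asks for a larger
  bandwidth.
* **Solver.** The 2×2 weighted normal equations are solved in closed form,
  vectorised over anchors, with an eigenvalue-based condition check; anchors
  whose normal matrix exceeds condition 1e12 are re-solved by
  rank-revealing least squares on the sqrt-weighted design. Tests verify the
  closed-form path against independent per-anchor `lstsq` solves to 1e-8.
* **Diagnostics.** Residuals are on the natural-log scale of the model (a
  relative-error view `exp(ε)-1` is also written by the CLI); global R² uses
  the residuals evaluated with each anchor's own coefficients; the effective
  parameter count is the hat-matrix trace, `σ² = RSS/(n - tr S)`, and AICc
  follows the standard corrected small-sample form
  `n ln(RSS/n) + n ln 2π + n(n + tr S)/(n - 2 - tr S)`. The local weighted
  R² is clamped to [0, 1] with the raw value reported alongside and clamp
  events logged. A constant response makes TSS zero; R² is then reported as
  0 with a warning, never NaN.

## Synthetic scenarios

The generator emulates the structure of a national LBS feed joined with
sample-survey statistics, at desk scale:

* **Truth surface.** A constant background (default 5 persons/cell) plus
  Gaussian-bump hotspots (default 12 bumps, peaks 250–500 persons/cell,
  radii 3–10 cells) — the clustered, hotspot-dominated pattern real
  population grids show.
* **Coefficient fields.** `a(u)` and `b(u)` are bilinear ramps along
  opposite diagonals (defaults 0.8→1.2 and 0→1), so spatial heterogeneity is
  visible to the local fit and recovery errors are interpretable; a
  smoothed-random-field mode exists for less structured heterogeneity.
* **Counts.** The expected count of cell *j* inverts the cell-level law,
  `T_j = exp((ln P_j - b_j)/a_j)`, evaluated on the *smooth* population
  component. The cell-level dispersion `noise_sigma` (log-normal, default
  0.1) enters the recorded truth only: it models the imperfection of LBS
  counts as a population proxy, so with `noise_sigma = 0` the law is exact
  in the truth and the pipeline's exact-recovery tests apply. Each day
  multiplies the expected counts by per-cell log-normal noise
  (`day_sigma`, default 0.05); holiday dates are additionally inflated by a
  constant factor (default 3), which the calendar filter must remove.
  Counts are real-valued by default (the pipeline operates on averages);
  a Poisson flag adds integer sampling noise.
* **Partitions.** Counties grow from random seed cells by nearest-seed
  assignment on the lattice (contiguous, full-coverage, deterministic per
  seed); towns are nested the same way inside each county. County and town
  statistics are exact sums of the truth surface, so conservation tests are
  integer-free. The default scenario is a 100×100 grid of 0.01° cells with
  400 counties, 4 towns per county, and 30 days containing 4 holidays —
  small enough that the full 20-seed acceptance batch runs in well under a
  minute, large enough that counties average ~25 cells and the town level
  is genuinely finer than the fitting level.

What the generator does **not** emulate: diurnal cycles, human mobility
between cells, market-share gradients of the LBS provider, census
undercount. Passing tests therefore demonstrate the correctness and the
statistical behaviour of the pipeline under a known generative model, not
the accuracy of any particular real-world product.

A second generator, `generate_coefficient_table`, draws county tables
directly from the log-linear law (random anchors, ramp coefficient fields,
uniform log-counts, Gaussian relation noise) with no aggregation step. It is
the clean benchmark for coefficient recovery and for the bandwidth/oracle
equivalence tests.

## Numerical conventions

* Grid row 0 is the northernmost row; cell boxes are half-open (west and
  north edges included) so every point belongs to exactly one cell.
* In-memory rasters mark nodata as NaN; the sentinel value is only an
  on-disk encoding. In the temporal mean a cell that is nodata on any
  included day is nodata ("strict"); a "mean over available days" mode is
  available but never fabricates full coverage silently.
* County conservation is enforced to ≤1e-6 relative (measured at ~1e-16);
  aggregating the allocation back to its source counties and scoring it is
  the validation fixed point (MSE 0, R² 1, slope 1).
* Validation populations are divided by 1e4 persons before the MSE; town
  MSE magnitudes in conventional reports are only plausible on that scale.
  The through-origin slope `Σ(est·ref)/Σ(est²)` matches a y≈x comparison;
  an intercept-including fit is reported alongside.

## Known limitations

* **Recovery bias under smooth regressors.** When the regressor field is
  spatially smooth, its local variation is collinear with the coefficient
  gradients, and local slopes absorb a term proportional to
  (coefficient gradient) × (regressor level) / (regressor gradient) that
  does not vanish with bandwidth. On full scenarios this, plus the
  county-aggregation bias (the sum of a cell-level log-linear law is not
  log-linear), puts a floor of roughly 0.05 on the median error of the
  recovered exponent regardless of the noise level. The noise-trend
  property is therefore asserted on the aggregation-free benchmark tables,
  where the error is noise-dominated and decreases monotonically with the
  relation noise.
* GeoTIFF support covers single-band geographic rasters with an axis-aligned
  geotransform; rotated transforms and projected CRSs are rejected
  explicitly. Vector input is GeoJSON.
* The regression is univariate by design; additional covariates, mixed
  GWR, and significance tests for local coefficients are out of scope, as
  are sub-daily population surfaces and ancillary masks (land cover,
  built-up area).
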