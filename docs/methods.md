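# Methods

`mobigrid` quantifies socio-spatial disparities in the decline of urban
activity during a mobility-restricting event (the motivating case is the
spring-2020 COVID-19 lockdown in a large city). The pipeline turns raw
smartphone location pings into a privacy-preserving gridded activity index,
validates that index against external mobility metrics, attaches
geodemographic context to grid cells, and estimates per-group deviations
from the regional average with a segmented regression. This note documents
the model, its assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## 1. From pings to a gridded activity index

A *ping* is one timestamped location observation (device id, app id, UTC
timestamp, position, horizontal GPS accuracy in metres). The filter cascade
is:

1. **Accuracy filter** — records with accuracy over `max_accuracy_m`
   (default 200 m) are discarded. The bound is read strictly: a record at
   exactly 200 m is retained.
2. **App-consistency filter** — an app is retained only if it has pings in
   at least `min_months_present` calendar months of the study window
   (default: all of them) and on at least `min_days_present` distinct days
   (default 30). This removes "temporary" apps that contribute bursts of
   data for a few weeks and would otherwise make the device panel lurch.
   No canonical numeric rule exists for "in use consistently"; both
   thresholds are configuration.
3. **Grid assignment** — positions are replaced by the id of the 1 km x 1 km
   cell containing them. Cells are half-open,
   `[x0, x0+1000) x [y0, y0+1000)`, so every point maps to exactly one cell.
4. **Hourly unique devices** — per (cell, date, hour), the number of
   distinct devices observed. A device pinging many times in one cell-hour
   counts once; a device visiting two cells in an hour counts once in each.
   This is the privacy boundary: after this step no trajectory exists.
5. **Daily activity** — the sum of the 24 hourly unique-device counts. It
   always lies between the day's distinct device count and 24 times it.
6. **Low-activity cell filter** — cells whose daily unique-device count
   never reaches `min_devices` (default 10) on any single day are removed;
   tiny denominators otherwise explode when converted to percentages. The
   rule is a max-scan (never reaches 10), not an any-day exclusion, which
   would empty the grid during the restriction period.

Day and hour boundaries are taken in a configurable timezone (`tz`); the
synthetic studies use UTC, which is also the timestamp storage convention.

## 2. Percent-of-baseline rescaling

Two baseline conventions coexist, mirroring the two families of public
mobility reports:

* **Weekday-median** (the Google Community Mobility Reports convention):
  `pct(d) = 100 * value(d) / median of the same weekday over the baseline
  window`. This removes the weekly cycle. Two windows are used: 3 Jan–6 Feb
  2020 for cross-source comparison, 6 Jan–8 Mar 2020 for the case-study
  analysis; both are configuration, neither is hard-coded.
* **Single reference day** (the Apple Mobility Trends convention):
  `pct(d) = 100 * value(d) / value(ref_date)`, which preserves weekly
  cycles. Harmonisation re-rescales such a series with the weekday-median
  convention over a shortened window.

Series with a zero weekday median are non-rescalable and are excluded with
a report rather than raising a division error. Missing cell-days are
zero-filled before rescaling (a cell with no pings genuinely had no
observed activity); missing dates of *external* report series are filled by
linear interpolation restricted to interior gaps (no extrapolation).

The regional reference series is the weekday-median rescale of the
**summed** daily activity over all included cells ("region-total"). The
alternative "mean-of-pcts" (the daily mean of per-cell percentages) is
available behind a flag. Region-total is the default because the regional
index should track where activity actually happens rather than weighting a
near-empty cell equally with a transport hub.

## 3. Cross-validation by hierarchical clustering

Date-aligned percent-of-baseline series (the panel index next to external
metrics, or per-category mean series in synthetic runs) are compared by
Euclidean distance on a fixed window (default 2 Mar–13 Jul) and
agglomerated with unweighted average linkage (UPGMA). Average linkage is
used because outlying series are deliberately retained — they carry the
information about how differently a metric reacts to shocks — and single
or Ward linkage are fragile in their presence. Distances are computed on
`pct` levels without standardisation. Ties in the minimum inter-cluster
distance are resolved by feeding leaves in lexicographic label order, which
makes the merge sequence deterministic and order-invariant up to that rule.
The dendrogram exports to Newick with branch lengths equal to merge-height
drops.

## 4. Linking geodemographic classifications to cells

Classification units rarely nest in grid cells, so each unit is represented
by its population-weighted centroid, assigned by point-in-cell to the single
cell containing it, carrying its weight (residential population for
residential classifications and deprivation deciles; workplace counts for
workplace classifications). Each cell takes the category with the largest
summed weight; ties break to the lexicographically smallest category; cells
receiving no centroid are labelled `n/a` and excluded from regression.
Retail typologies are not population-based and are assigned by largest
polygon–cell overlap area instead. Deprivation deciles are treated as ten
ordinal categories.

Two diagnostics evaluate the linkage: the Pearson correlation between cell
weights and mean pre-restriction daily activity (daytime-population weights
should correlate more strongly than residential weights when the panel
tracks ambient population), and the signed percentage-point discrepancy per
category between gridded areal shares and original-unit areal shares
(dominant-category assignment over-represents small, heavy units embedded
in larger zones).

## 5. Segmented deviation regression

The study period is partitioned into five policy segments (2020): baseline
5 Jan–8 Mar, pre-restriction behaviour change 9–22 Mar, full restriction
23 Mar–9 May, first easing 10 May–13 Jun, second easing 14 Jun–13 Jul. The
boundary day 14 June belongs to the second easing phase, so the segments
partition the window exactly; all dates are configuration.

The response is the cell-day deviation `dev_pp(c, d) = pct(c, d) −
pct_ref(d)` in percentage points. Separately per classification scheme, an
ordinary least squares regression of the deviations on the full set of
category x segment indicators *without intercept* estimates each group's
mean deviation per segment; a significantly positive coefficient means the
group stayed relatively busier than the region in that segment. Per-segment
adjusted R² comes from a segment-restricted one-way categorical subfit
(centred total sum of squares), and per-segment significance maps label
each cell `sig_positive` / `sig_negative` / `not_significant` / `n/a`.

**Observation unit.** By default each cell contributes one observation per
segment — the mean of its daily deviations in that segment — rather than
one per day. The reason is a variance component the daily design ignores:
the weekday-median baseline is estimated from ~9 values per weekday, and
its estimation error leaves a *persistent* multiplicative offset in every
rescaled value of that cell. Daily deviations within a cell are therefore
serially correlated, and classical standard errors on cell-days overstate
significance (measured on null simulations: a 10.9% rejection rate at a
nominal 5%). Averaging to cell-segment means puts that persistent component
into each observation exactly once; observations within a coefficient are
then independent across cells, and the measured null rejection rate is 5.0%.
The cell-day unit remains available (`unit="cell-day"`), as do
heteroskedasticity-robust and cluster-by-cell covariances; cluster-robust
errors need many cells per category and degenerate at desk scale.

No multiple-testing correction is applied, temporal and spatial
autocorrelation are not modelled, and estimates are reported on the
percentage-point scale — all deliberate, documented limitations of the
method as specified.

## 6. Synthetic data generator

Real app-SDK panels, and the external report feeds, are proprietary, so the
generator emulates the statistical structure the analysis assumes:

* **Zones** — a rectangular tessellation of an `area_km` x `area_km` square
  (default 10 x 10 km) into `n_zones` rectangles (default 8); log-normal
  weights (median 1000, sigma 0.5); categories assigned cyclically then
  shuffled; the population-weighted centroid is drawn uniformly from the
  central 70% of the rectangle.
* **Panel** — `n_devices` devices (default 200), balanced in equal numbers
  across categories and placed, within a category, in zones with
  probability proportional to weight; homes scatter N(0, 100 m) around the
  zone centroid. Daily activity probabilities are Beta(2, ·) with mean 8/30
  — about eight active days per month, matching what a consistently
  observed consumer panel delivers. Each device holds 1–3 apps from a pool
  of 20, always at least one persistent app; 30% of the pool is
  "temporary", emitting only during a random 14-day window, to exercise
  the consistency filter.
* **Pings** — a device-day is active with probability
  `min(1, p_device * multiplier(category, segment))`; the planted
  multiplier schedule is the recoverable ground truth. Active days emit
  Poisson(20) pings with N(0, 300 m) scatter around home and
  uniform-in-day timestamps. GPS accuracy is log-normal (median 25 m,
  capped at 200 m), pushed strictly above 200 m with probability
  `tail_prob` (default 0.05) to exercise the accuracy filter. Device-day
  activations are independent; everything is deterministic given the seed.

The spatial concentration of homes around centroids is what lets any cell
survive the 10-device filter at a 200-device panel; cells away from
centroids are excluded, which also exercises the `n/a` path of the linkage.

**Ground truth for recovery.** The expected deviation of a category with
multiplier `m` in a segment is `100 * (m − w̄)`, where `w̄` is the
activity-share-weighted mean multiplier of the segment (the regional
reference moves with the planted effects). The default planted schedules
are balanced — one category below 1, one above, shares equal — so `w̄ ≈ 1`
and the truth is `(m − 1) * 100` percentage points. The helper
`synth.expected_deviation_pp` computes the exact model-implied truth for
arbitrary schedules.

**What the generator does not emulate** (hence what passing tests do not
show about real data): tourist/resident composition, road-network-
constrained movement, inter-day dependence of device activity, device churn
across the panel, spatially varying GPS quality, or the marginal totals of
any real panel. Recovery results certify the estimator under the generative
assumptions, not the representativeness of any real feed.

## 7. Numerical choices and degenerate inputs

* Medians are plain sample medians (even counts average the middle pair);
  with an odd number of weekday occurrences the baseline-window weekday
  median of a rescaled series is exactly 100 by construction.
* The no-intercept indicator design makes OLS coefficients equal group
  means to machine precision; this closed form is the test oracle, while
  the implementation goes through the OLS machinery to obtain inference.
* Category x segment combinations with no observations are reported as
  missing (NaN), never as zero. Cells with zero weekday-median baselines
  are excluded with a report, never a division error.
* Confidence intervals use the fitted model's t quantiles, not the normal
  approximation.
* A filter that removes every record aborts the pipeline with a stage
  error carrying the filter report (exercised by the zero-accuracy-cutoff
  degenerate cascade).
* Simulation studies are sized for a single CPU: the recovery study uses
  20 replicates of the 200-device default, the calibration study 50
  replicates; both sizes are stated choices of the package's validation
  design.

## 8. Known limitations

* At desk scale only a handful of cells per category survive the 10-device
  filter, so per-category standard errors are wide (~3–7 pp); the planted
  ±20 pp effects are comfortably detectable, ±9 pp effects need the larger
  (16-zone, 400-device) pattern configuration.
* The weekday-median inflation of low-count cells relative to the
  region-total reference leaves a small (~2 pp) common positive bias in
  deviations at the default panel size; it shrinks with per-cell counts
  and largely cancels between categories.
* The grid origin is fixed, not optimised; results inherit the modifiable
  areal unit problem of any gridded analysis.
* Area-level estimates describe areas, not individuals (ecological
  fallacy).
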