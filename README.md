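# mobigrid

Socio-spatial analysis of activity decline from smartphone location pings.

Crowd-level app-SDK location data can show *which neighbourhoods* kept
moving and which went quiet when mobility restrictions hit a city — but
only after heavy preprocessing: the raw pings are noisy, app coverage
churns, and nothing may be published that could reconstruct a trajectory.
`mobigrid` implements that full path for researchers in urban analytics and
public health:

1. **Filter & aggregate** — discard pings with GPS accuracy over 200 m,
   keep only apps in use consistently through the study period, spatially
   join pings to a 1 km² grid, count *unique devices per cell per hour*,
   and sum the 24 hourly counts into a daily activity level. Cells never
   visited by 10 unique devices on any day are excluded. After this step
   no individual traces exist.
2. **Rescale** — convert daily activity to a percent-of-baseline index,
   `pct(d) = 100 · a(d) / median_weekday-of-d(baseline window)` (the
   Community-Mobility-Reports convention, which removes the weekly cycle),
   or relative to a single reference day (the Mobility-Trends convention).
   A regional reference series is built the same way from the region-total
   activity.
3. **Cross-validate** — compare index series by Euclidean distance over a
   fixed window and cluster them with average-linkage (UPGMA) hierarchical
   clustering; export the dendrogram as Newick.
4. **Link geodemographics** — assign each grid cell the dominant category
   of a classification scheme via population-weighted centroids (or
   largest area overlap for retail typologies), with correlation and
   areal-share diagnostics.
5. **Segmented regression** — split the study period into five policy
   segments and regress cell deviations from the regional reference,
   `dev(c,d) = pct(c,d) − pct_ref(d)`, on category × segment indicators
   without intercept, so each coefficient is a group's mean deviation (in
   percentage points) from the regional average in that segment, with
   per-segment adjusted R² and a cell-level significance map.

Because real ping feeds are proprietary, the package ships a first-class
synthetic generator (`mobigrid.synth`): zone tessellations with
population-weighted centroids, a device panel with realistic activity
calendars and app churn, and planted category × segment activity
multipliers that the regression must recover. Every stage is validated
against that planted truth.

The statistical cores are scikit-learn-style estimators —
`WeekdayMedianRescaler`, `SingleDayRescaler` (fit/transform),
`AverageLinkageClustering`, `SegmentedDeviationRegression` (fit, fitted
attributes with trailing underscores) — with plain functions as thin
wrappers, plus a `mobigrid` CLI
(`simulate | ingest | aggregate | rescale | compare | link | segreg | run`).

## Worked example

Plant the qualitative pattern observed in the motivating case study —
deprivation-linked neighbourhoods staying relatively busier than the
regional average during the restriction segment, affluent neighbourhoods
declining more, nothing happening in the baseline segment — and recover it
end to end:

```python
from mobigrid import synth
from mobigrid.pipeline import RunConfig, execute

deprived  = ["deprived_1", "deprived_2"]
affluent  = ["affluent_1", "affluent_2"]
mixed     = ["mixed_1", "mixed_2"]
cfg = RunConfig(seed=11, n_zones=16, n_devices=400,
                categories=deprived + affluent + mixed,
                schedule=synth.lockdown_pattern_schedule(
                    deprived, affluent, mixed).to_dict())
res = execute(cfg)

est = res["estimates"]
print(est[est.segment_id == 3]          # segment 3 = full restriction
      [["category", "estimate_pp", "std_err", "p_value", "significant"]]
      .round(2).to_string(index=False))
```

```
  category  estimate_pp  std_err  p_value  significant
affluent_1       -10.26     3.73     0.01         True
affluent_2        -8.58     3.73     0.03         True
deprived_1         8.96     3.73     0.02         True
deprived_2        12.35     3.04     0.00         True
   mixed_1         0.04     3.73     0.99        False
   mixed_2         1.02     3.73     0.78        False
```

The planted truths are ±9 pp (deprived at 1.5× and affluent at 0.5× the
regional activity level during the restriction segment): both deprived
categories come out significantly positive, both affluent ones
significantly negative, the unplanted categories are null, and no baseline
coefficient is significant. Per-segment fit quality follows the expected
shape — the model explains little during the baseline (adjusted R² 0.22,
when all groups track the region) and most of the variation once the
restrictions differentiate the groups (0.88 in the restriction segment):

```
   scheme  segment_id  adj_r2  n_obs
synthetic           1   0.222     13
synthetic           2   0.918     13
synthetic           3   0.879     13
synthetic           4   0.973     13
synthetic           5   0.870     13
```

`mobigrid run --config cfg.yaml --seed 11 --out runs/demo` performs the
same analysis from the shell, writing per-stage CSV/GeoJSON artifacts and
a manifest whose outputs are bit-identical for identical config and seed.

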