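"""Synthetic device panels, ping tables and zone layers with planted effects.

The generator emulates the statistical structure an app-SDK mobility panel
is assumed to have, so every downstream stage is testable without any
proprietary feed:

* a rectangular tessellation of the study area into zones, each carrying a
  classification category, a log-normal weight (residents or workplaces) and
  a population-weighted centroid inside the zone;
* a device panel with homes clustered around zone centroids, 1-3 apps per
  device (a configurable fraction of apps are "temporary" and emit only
  during a random two-week window), and per-device daily activity
  probabilities averaging ~8 active days per month;
* per device-day Bernoulli activation whose probability is multiplied by a
  planted (category, segment) activity multiplier — the ground truth that
  the segmented regression must recover; active days emit a Poisson number
  of pings with Gaussian scatter around home, timestamps uniform over the
  day, and a heavy-tailed GPS accuracy draw with a configurable exceedance
  probability above the 200 m filter cutoff.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from mobigrid.errors import ParameterError
from mobigrid.segreg import SegmentDefinition, segment_of

ACCURACY_CUTOFF_M = 200.0


@dataclass(frozen=True)
class Zone:
    """One areal unit: polygon, classification category, weight and
    population-weighted centroid (always inside the polygon)."""

    zone_id: str
    polygon: Polygon
    category: str
    weight: float
    centroid: Point


@dataclass
class EffectSchedule:
    """Planted multiplicative activity levels per (category, segment).

    ``multiplier(cat, seg)`` defaults to 1.0 for pairs not listed. The
    baseline segment must stay at 1 so percent-of-baseline rescaling has a
    well-defined reference level.
    """

    entries: dict[tuple[str, int], float] = field(default_factory=dict)
    baseline_segment: int = 1

    def __post_init__(self):
        for (cat, seg), m in self.entries.items():
            if m <= 0:
                raise ParameterError(f"multiplier for ({cat}, {seg}) must be > 0, got {m}")
            if seg == self.baseline_segment and m != 1.0:
                raise ParameterError(
                    f"baseline segment {seg} multiplier for {cat} must be 1, got {m}"
                )

    def multiplier(self, category: str, segment_id: int) -> float:
        return self.entries.get((category, segment_id), 1.0)

    def to_dict(self) -> dict:
        return {
            "baseline_segment": self.baseline_segment,
            "entries": [
                {"category": c, "segment_id": s, "multiplier": m}
                for (c, s), m in sorted(self.entries.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSchedule":
        entries = {
            (e["category"], int(e["segment_id"])): float(e["multiplier"])
            for e in d.get("entries", [])
        }
        return cls(entries=entries, baseline_segment=int(d.get("baseline_segment", 1)))


@dataclass
class DevicePanel:
    """Columnar container for the synthetic device panel."""

    device_id: np.ndarray          # str
    home_x: np.ndarray             # metres
    home_y: np.ndarray
    home_category: np.ndarray      # category of home zone
    home_zone: np.ndarray          # zone_id of home zone
    daily_activity_prob: np.ndarray
    apps: list[list[str]]          # >= 1 app per device
    app_windows: dict[str, tuple[date, date] | None]  # None = consistent app

    def __len__(self) -> int:
        return len(self.device_id)

    @property
    def temporary_apps(self) -> list[str]:
        return sorted(a for a, w in self.app_windows.items() if w is not None)


def generate_zones(n_zones: int, categories: list[str], area_km: float,
                   seed: int) -> list[Zone]:
    """Tessellate an area_km x area_km study square into n_zones rectangles.

    Rows of near-equal height are split into rectangles so the union covers
    the square exactly; weights are log-normal, categories are assigned
    cyclically then shuffled, and each centroid is drawn uniformly from the
    central 70% of its rectangle (guaranteeing containment).
    """
    if n_zones <= 0 or area_km <= 0:
        raise ParameterError("n_zones and area_km must be positive")
    if n_zones < len(categories):
        raise ParameterError("need at least one zone per category")
    if area_km < 2:
        raise ParameterError("area_km must be >= 2")
    rng = np.random.default_rng(seed)
    side = area_km * 1000.0

    n_rows = max(1, int(math.floor(math.sqrt(n_zones))))
    base, extra = divmod(n_zones, n_rows)
    cols_per_row = [base + (1 if r < extra else 0) for r in range(n_rows)]
    row_h = side / n_rows

    cats = [categories[i % len(categories)] for i in range(n_zones)]
    cats = list(rng.permutation(np.array(cats, dtype=object)))
    weights = np.round(rng.lognormal(mean=math.log(1000.0), sigma=0.5, size=n_zones))

    zones: list[Zone] = []
    k = 0
    for r, ncols in enumerate(cols_per_row):
        y0, y1 = r * row_h, (r + 1) * row_h
        col_w = side / ncols
        for c in range(ncols):
            x0, x1 = c * col_w, (c + 1) * col_w
            poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
            cx = x0 + col_w * (0.15 + 0.70 * rng.random())
            cy = y0 + row_h * (0.15 + 0.70 * rng.random())
            zones.append(Zone(
                zone_id=f"Z{k:04d}", polygon=poly, category=str(cats[k]),
                weight=float(weights[k]), centroid=Point(cx, cy),
            ))
            k += 1
    return zones


def generate_panel(n_devices: int, zones: list[Zone], calendar: pd.DatetimeIndex,
                   seed: int, n_apps: int = 20, temporary_fraction: float = 0.3,
                   home_scatter_m: float = 100.0,
                   mean_active_days_per_month: float = 8.0) -> DevicePanel:
    """Draw a device panel with homes clustered around zone centroids.

    Device counts are balanced across classification categories (so the
    region-wide mean of any planted category multiplier equals the plain
    category average); within a category, a device's zone is chosen with
    probability proportional to zone weight. Daily activity probabilities
    are Beta-distributed with mean ``mean_active_days_per_month / 30``.
    Each device holds 1-3 apps, always at least one consistent app;
    temporary apps emit only during a random 14-day window of the calendar.
    """
    if n_devices <= 0:
        raise ParameterError("n_devices must be positive")
    if not zones:
        raise ParameterError("zones must be non-empty")
    rng = np.random.default_rng(seed)

    cats = sorted({z.category for z in zones})
    zones_by_cat = {c: [z for z in zones if z.category == c] for c in cats}

    # app pool: first app forced consistent so every device can carry one
    app_ids = [f"app{i:03d}" for i in range(n_apps)]
    n_temp = min(int(round(temporary_fraction * n_apps)), n_apps - 1)
    temp_ids = set(rng.choice(app_ids[1:], size=n_temp, replace=False)) if n_temp else set()
    days = calendar.normalize().unique().sort_values()
    app_windows: dict[str, tuple[date, date] | None] = {}
    for a in app_ids:
        if a in temp_ids and len(days) > 14:
            start_idx = int(rng.integers(0, len(days) - 14))
            app_windows[a] = (days[start_idx].date(), days[start_idx + 13].date())
        else:
            app_windows[a] = None
    consistent = [a for a in app_ids if app_windows[a] is None]

    cat_idx = rng.permuted(np.arange(n_devices) % len(cats))
    p_mean = mean_active_days_per_month / 30.0
    # Beta with fixed a=2 matches the target mean with realistic dispersion
    a_shape = 2.0
    b_shape = a_shape * (1.0 - p_mean) / p_mean
    probs = np.clip(rng.beta(a_shape, b_shape, size=n_devices), 0.02, 1.0)

    hx = np.empty(n_devices)
    hy = np.empty(n_devices)
    hcat = np.empty(n_devices, dtype=object)
    hzone = np.empty(n_devices, dtype=object)
    apps: list[list[str]] = []
    minx = min(z.polygon.bounds[0] for z in zones)
    miny = min(z.polygon.bounds[1] for z in zones)
    maxx = max(z.polygon.bounds[2] for z in zones)
    maxy = max(z.polygon.bounds[3] for z in zones)
    for i in range(n_devices):
        cat = cats[cat_idx[i]]
        zs = zones_by_cat[cat]
        w = np.array([z.weight for z in zs], dtype=float)
        z = zs[rng.choice(len(zs), p=w / w.sum())]
        hx[i] = np.clip(z.centroid.x + rng.normal(0, home_scatter_m), minx, maxx - 1e-6)
        hy[i] = np.clip(z.centroid.y + rng.normal(0, home_scatter_m), miny, maxy - 1e-6)
        hcat[i] = z.category
        hzone[i] = z.zone_id
        k = int(rng.integers(1, 4))
        chosen = [str(rng.choice(consistent))]
        if k > 1:
            pool = [a for a in app_ids if a not in chosen]
            chosen += list(rng.choice(pool, size=k - 1, replace=False))
        apps.append(chosen)

    return DevicePanel(
        device_id=np.array([f"D{i:06d}" for i in range(n_devices)]),
        home_x=hx, home_y=hy, home_category=hcat, home_zone=hzone,
        daily_activity_prob=probs, apps=apps, app_windows=app_windows,
    )


def generate_pings(panel: DevicePanel, zones: list[Zone], calendar: pd.DatetimeIndex,
                   schedule: EffectSchedule, segments: list[SegmentDefinition],
                   accuracy_params: tuple[float, float] = (25.0, 0.05),
                   seed: int = 0, mean_pings_per_active_day: float = 20.0,
                   scatter_m: float = 300.0,
                   return_device_days: bool = False):
    """Emit the synthetic ping table for a panel over a calendar.

    Per device-day the activation probability is
    ``min(1, daily_activity_prob * multiplier(home category, segment))``;
    active days emit ``Poisson(mean_pings_per_active_day)`` pings scattered
    ``Normal(0, scatter_m)`` around home, with uniform-in-day timestamps.
    GPS accuracy is log-normal (median ``accuracy_params[0]`` m, capped at
    200 m) except with probability ``accuracy_params[1]`` the draw is pushed
    strictly above 200 m to exercise the accuracy filter.

    Returns the ping frame (device_id, app_id, timestamp, x_m, y_m,
    accuracy_m); with ``return_device_days=True`` also a per-active-device-day
    frame (device_id, date, n_pings) for conservation checks.
    """
    if len(panel) == 0:
        raise ParameterError("panel is empty")
    days = calendar.normalize().unique().sort_values()
    seg_ids = segment_of(days.date, segments)
    if seg_ids.isna().any():
        bad = days[np.asarray(seg_ids.isna())][0]
        raise ParameterError(f"calendar date {bad.date()} lies outside all segments")
    seg_ids = seg_ids.astype(int).to_numpy()
    body_scale, tail_prob = accuracy_params
    if not 0 <= tail_prob <= 1:
        raise ParameterError(f"tail_prob must be in [0,1], got {tail_prob}")

    rng = np.random.default_rng(seed)
    cats = sorted({z.category for z in zones})
    cat_to_i = {c: i for i, c in enumerate(cats)}
    seg_set = sorted({s.segment_id for s in segments})
    seg_to_i = {s: i for i, s in enumerate(seg_set)}
    mult = np.ones((len(cats), len(seg_set)))
    for c in cats:
        for s in seg_set:
            mult[cat_to_i[c], seg_to_i[s]] = schedule.multiplier(c, s)

    dev_cat = np.array([cat_to_i[c] for c in panel.home_category])
    day_seg = np.array([seg_to_i[s] for s in seg_ids])
    p = np.clip(panel.daily_activity_prob[:, None] * mult[dev_cat][:, day_seg], 0.0, 1.0)
    active = rng.random(p.shape) < p
    dev_i, day_i = np.nonzero(active)
    n_pings = rng.poisson(mean_pings_per_active_day, size=len(dev_i))

    # per active device-day, pings flow through one app available that day
    day_dates = np.array([d.date() for d in days], dtype=object)
    app_choice = np.empty(len(dev_i), dtype=object)
    for j in range(len(dev_i)):
        d = day_dates[day_i[j]]
        avail = [a for a in panel.apps[dev_i[j]]
                 if panel.app_windows[a] is None
                 or panel.app_windows[a][0] <= d <= panel.app_windows[a][1]]
        app_choice[j] = avail[int(rng.integers(0, len(avail)))]

    rep = np.repeat(np.arange(len(dev_i)), n_pings)
    n_total = len(rep)
    x = panel.home_x[dev_i][rep] + rng.normal(0, scatter_m, size=n_total)
    y = panel.home_y[dev_i][rep] + rng.normal(0, scatter_m, size=n_total)
    secs = rng.random(n_total) * 86400.0
    ts = (days.tz_localize("UTC")[day_i][rep]
          + pd.to_timedelta(np.round(secs, 3), unit="s"))
    acc = np.minimum(rng.lognormal(math.log(body_scale), 0.9, size=n_total),
                     ACCURACY_CUTOFF_M)
    tail = rng.random(n_total) < tail_prob
    if tail.any():
        acc[tail] = ACCURACY_CUTOFF_M * (1.0 + rng.exponential(0.5, size=int(tail.sum())))

    pings = pd.DataFrame({
        "device_id": panel.device_id[dev_i][rep],
        "app_id": app_choice[rep],
        "timestamp": ts,
        "x_m": x,
        "y_m": y,
        "accuracy_m": acc,
    }).sort_values("timestamp", kind="stable").reset_index(drop=True)

    if return_device_days:
        dd = pd.DataFrame({
            "device_id": panel.device_id[dev_i],
            "date": day_dates[day_i],
            "n_pings": n_pings,
        })
        return pings, dd
    return pings


def expected_deviation_pp(panel: DevicePanel, schedule: EffectSchedule,
                          segments: list[SegmentDefinition]) -> pd.DataFrame:
    """Model-implied truth: per (category, segment) deviation in percentage
    points of the category's expected percent-of-baseline level from the
    region-total reference level.

    The reference level of a segment is the activity-share-weighted mean of
    the category multipliers, where a category's share is the sum of its
    devices' daily activity probabilities; the deviation is
    ``100 * (multiplier - reference_level)``.
    """
    cats = sorted(set(panel.home_category))
    share = {c: panel.daily_activity_prob[panel.home_category == c].sum() for c in cats}
    total = sum(share.values())
    rows = []
    for seg in segments:
        ref = sum(share[c] / total * schedule.multiplier(c, seg.segment_id) for c in cats)
        for c in cats:
            m = schedule.multiplier(c, seg.segment_id)
            rows.append((c, seg.segment_id, m, 100.0 * (m - ref)))
    return pd.DataFrame(rows, columns=["category", "segment_id", "multiplier", "truth_pp"])


def null_schedule() -> EffectSchedule:
    """All multipliers 1 — no planted effects (type-I calibration runs)."""
    return EffectSchedule()


def recovery_schedule(categories: list[str], segment_id: int = 3,
                      low: float = 0.8, high: float = 1.2) -> EffectSchedule:
    """One category planted below the region, one above, rest at 1.

    With a category-balanced panel the region mean multiplier stays ~1, so
    the planted truths are (low-1)*100 and (high-1)*100 percentage points.
    """
    if len(categories) < 2:
        raise ParameterError("need at least two categories")
    return EffectSchedule(entries={
        (categories[0], segment_id): low,
        (categories[1], segment_id): high,
    })


def lockdown_pattern_schedule(deprived: list[str], affluent: list[str],
                              others: list[str] | None = None) -> EffectSchedule:
    """Plant the qualitative lockdown pattern: a region-wide collapse during
    segments 2-5 in which deprivation-linked categories stay relatively
    busier than the regional average and affluent categories decline more,
    with no effects in the baseline segment and a partial recovery in the
    easing segments."""
    others = others or []
    entries: dict[tuple[str, int], float] = {}
    # region-wide level by segment: precaution, lockdown, easing 1, easing 2
    level = {2: 0.55, 3: 0.18, 4: 0.30, 5: 0.45}
    for seg, base in level.items():
        for c in deprived:
            entries[(c, seg)] = base * 1.5
        for c in affluent:
            entries[(c, seg)] = base * 0.5
        for c in others:
            entries[(c, seg)] = base
    return EffectSchedule(entries=entries)


def study_calendar(segments: list[SegmentDefinition] | None = None) -> pd.DatetimeIndex:
    """Daily calendar spanning the (default) study segments."""
    from mobigrid.segreg import default_segments
    segs = segments or default_segments()
    start = min(s.start_date for s in segs)
    end = max(s.end_date for s in segs)
    return pd.date_range(start, end, freq="D")


def zones_to_geojson(zones: list[Zone], polygon_path, centroid_path) -> None:
    """Write the zone layer as two FeatureCollections (polygons, centroids)."""
    from mobigrid.geo import write_geojson
    write_geojson(polygon_path, [
        (z.polygon, {"zone_id": z.zone_id, "category": z.category, "weight": z.weight})
        for z in zones
    ])
    write_geojson(centroid_path, [
        (z.centroid, {"zone_id": z.zone_id, "weight": z.weight}) for z in zones
    ])
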