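"""The filter cascade and 1 km^2 grid aggregation.

Order of the cascade: GPS-accuracy filter -> app-consistency filter ->
grid assignment -> hourly unique-device counts -> daily activity ->
low-activity cell exclusion. The accuracy and app filters are row/app-level
predicates independent of each other, so they commute; the cell filter is
applied last because it needs the full study period.

Privacy model: once pings are replaced by (cell, date, hour, n_devices)
counts no trajectory can be reconstructed — a device is only known to have
been in a cell within an hour, not for how long or on what path.
"""

from __future__ import annotations

import pandas as pd

from mobigrid.errors import ParameterError
from mobigrid.geo import point_cell_id

DEFAULT_MAX_ACCURACY_M = 200.0
DEFAULT_MIN_DEVICES = 10
CELL_SIZE_M = 1000.0


def filter_accuracy(pings: pd.DataFrame,
                    max_accuracy_m: float = DEFAULT_MAX_ACCURACY_M
                    ) -> tuple[pd.DataFrame, dict]:
    """Drop observations whose GPS accuracy exceeds the cutoff.

    The cutoff is read strictly ("over 200 m" is dropped), so a record at
    exactly 200 m is retained.
    """
    keep = pings["accuracy_m"] <= max_accuracy_m
    report = {"filter": "accuracy", "input_rows": len(pings),
              "kept": int(keep.sum()), "removed": int((~keep).sum()),
              "max_accuracy_m": max_accuracy_m}
    return pings[keep].reset_index(drop=True), report


def filter_consistent_apps(pings: pd.DataFrame, calendar: pd.DatetimeIndex,
                           min_months_present: int | None = None,
                           min_days_present: int = 30
                           ) -> tuple[pd.DataFrame, list[str], dict]:
    """Retain only apps in use consistently throughout the study period.

    An app is retained iff it has at least one ping in at least
    ``min_months_present`` distinct calendar months (default: every month
    the calendar touches) and pings on at least ``min_days_present``
    distinct days. Temporary apps — live only for a short window — fail
    both and are excluded together with their pings.
    """
    if len(calendar) == 0:
        raise ParameterError("calendar is empty")
    cal_months = pd.PeriodIndex(calendar, freq="M").unique()
    if min_months_present is None:
        min_months_present = len(cal_months)

    ts = pd.to_datetime(pings["timestamp"], utc=True).dt.tz_localize(None)
    per_app = pd.DataFrame({
        "app_id": pings["app_id"],
        "month": ts.dt.to_period("M"),
        "day": ts.dt.date,
    })
    stats = per_app.groupby("app_id").agg(
        months=("month", "nunique"), days=("day", "nunique"))
    ok_apps = stats[(stats["months"] >= min_months_present)
                    & (stats["days"] >= min_days_present)].index
    excluded = sorted(set(stats.index) - set(ok_apps))
    keep = pings["app_id"].isin(ok_apps)
    report = {"filter": "consistent_apps", "input_rows": len(pings),
              "kept": int(keep.sum()), "removed": int((~keep).sum()),
              "apps_total": int(len(stats)), "apps_excluded": len(excluded),
              "min_months_present": int(min_months_present),
              "min_days_present": int(min_days_present)}
    return pings[keep].reset_index(drop=True), excluded, report


def assign_grid(pings: pd.DataFrame, origin: tuple[float, float] = (0.0, 0.0),
                cell_size_m: float = CELL_SIZE_M) -> pd.DataFrame:
    """Replace coordinates by a grid cell id on half-open 1 km cells.

    ``cell_id = floor((x - ox)/s) "_" floor((y - oy)/s)``; the half-open
    convention [x0, x0+s) x [y0, y0+s) maps every point to exactly one cell.
    """
    out = pings.copy()
    out["cell_id"] = point_cell_id(out["x_m"].to_numpy(), out["y_m"].to_numpy(),
                                   origin=origin, cell_size_m=cell_size_m)
    return out


def hourly_unique_devices(pings: pd.DataFrame, tz: str | None = None) -> pd.DataFrame:
    """Count distinct devices per (cell, date, hour).

    A device pinging several times in a cell within an hour counts once
    there; the same device appearing in two cells within the hour counts
    once in each. ``tz`` sets the timezone in which day/hour boundaries are
    taken (None: timestamps used as-is / UTC).
    """
    ts = pd.to_datetime(pings["timestamp"], utc=True)
    if tz is not None:
        ts = ts.dt.tz_convert(tz)
    df = pd.DataFrame({
        "cell_id": pings["cell_id"],
        "date": ts.dt.date,
        "hour": ts.dt.hour,
        "device_id": pings["device_id"],
    })
    out = (df.groupby(["cell_id", "date", "hour"])["device_id"]
             .nunique().rename("n_devices").reset_index())
    return out


def daily_activity(hourly: pd.DataFrame, pings: pd.DataFrame | None = None,
                   tz: str | None = None) -> pd.DataFrame:
    """Sum hourly unique-device counts into the daily activity level.

    ``activity`` is the sum over the 24 hours of the hourly unique-device
    counts; ``unique_devices`` is the number of distinct devices seen in
    the cell that day (computed from the ping table when provided, else
    bounded by the hourly maximum). Cell-days with no pings have no row
    and are treated as zero downstream.
    """
    act = (hourly.groupby(["cell_id", "date"])["n_devices"]
                 .sum().rename("activity").reset_index())
    if pings is not None:
        ts = pd.to_datetime(pings["timestamp"], utc=True)
        if tz is not None:
            ts = ts.dt.tz_convert(tz)
        uniq = (pd.DataFrame({"cell_id": pings["cell_id"], "date": ts.dt.date,
                              "device_id": pings["device_id"]})
                .groupby(["cell_id", "date"])["device_id"].nunique()
                .rename("unique_devices").reset_index())
        act = act.merge(uniq, on=["cell_id", "date"], how="left")
    else:
        mx = (hourly.groupby(["cell_id", "date"])["n_devices"]
                    .max().rename("unique_devices").reset_index())
        act = act.merge(mx, on=["cell_id", "date"], how="left")
    act["activity"] = act["activity"].astype(int)
    act["unique_devices"] = act["unique_devices"].astype(int)
    return act


def filter_low_activity_cells(daily: pd.DataFrame,
                              min_devices: int = DEFAULT_MIN_DEVICES
                              ) -> tuple[pd.DataFrame, list[str], dict]:
    """Exclude grid cells that never reach ``min_devices`` unique devices on
    any single day of the study period.

    Low-count cells produce unstable percentages when rescaled, so cells
    whose daily unique-device count never reaches the threshold are removed
    entirely.
    """
    peak = daily.groupby("cell_id")["unique_devices"].max()
    excluded = sorted(peak[peak < min_devices].index)
    keep = ~daily["cell_id"].isin(excluded)
    n_cells = int(peak.size)
    report = {"filter": "low_activity_cells", "cells_total": n_cells,
              "cells_excluded": len(excluded),
              "excluded_fraction": (len(excluded) / n_cells) if n_cells else 0.0,
              "min_devices": int(min_devices)}
    return daily[keep].reset_index(drop=True), excluded, report
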