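"""Percent-of-baseline rescaling of activity series.

Two baseline conventions coexist, mirroring the two families of public
mobility reports:

* weekday-median (Google convention): a day's value is expressed as a
  percentage of the median value of the same weekday over a fixed baseline
  window, removing the weekly cycle;
* single reference day (Apple convention): values relative to one date,
  preserving weekly cycles.

Rescaling is scale-invariant — multiplying a series by any c > 0 leaves
the percentages unchanged — and the per-weekday median of the baseline
window's percentages is exactly 100 for every rescalable series.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from mobigrid.errors import ParameterError

logger = logging.getLogger(__name__)


def _as_long(X: pd.DataFrame, series_col: str, value_col: str) -> pd.DataFrame:
    for col in (series_col, "date", value_col):
        if col not in X.columns:
            raise ParameterError(f"expected column '{col}' in series frame")
    out = X[[series_col, "date", value_col]].rename(
        columns={series_col: "series_id", value_col: "value"}).copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    return out


def zero_fill_daily(X: pd.DataFrame, calendar, series_col: str = "series_id",
                    value_col: str = "value") -> pd.DataFrame:
    """Complete a long series frame to the full calendar, filling absent
    series-days with 0 (a cell with no pings had no observed activity)."""
    long = _as_long(X, series_col, value_col)
    dates = pd.to_datetime(pd.Index(calendar)).normalize().unique()
    dates = sorted(d.date() for d in dates)
    full = pd.MultiIndex.from_product(
        [sorted(long["series_id"].unique()), dates], names=["series_id", "date"])
    out = (long.set_index(["series_id", "date"])["value"]
               .reindex(full, fill_value=0).reset_index())
    return out.rename(columns={"series_id": series_col, "value": value_col})


class WeekdayMedianRescaler(BaseEstimator, TransformerMixin):
    """Rescale long activity series to percent of weekday-median baseline.

    ``fit`` learns, per series and ISO weekday (1=Monday..7=Sunday), the
    median value over the baseline window; ``transform`` converts values to
    ``pct = 100 * value / baseline(weekday)``. Series with a zero (or
    missing) weekday median are flagged non-rescalable and dropped from the
    transform output with a report rather than raising a division error.

    Parameters
    ----------
    baseline_start, baseline_end : inclusive baseline window dates
    series_col, value_col : column names of the long input frame
    zero_fill : treat series-days absent from the baseline window as 0
    """

    def __init__(self, baseline_start=None, baseline_end=None,
                 series_col: str = "series_id", value_col: str = "value",
                 zero_fill: bool = True):
        self.baseline_start = baseline_start
        self.baseline_end = baseline_end
        self.series_col = series_col
        self.value_col = value_col
        self.zero_fill = zero_fill

    def fit(self, X: pd.DataFrame, y=None):
        if self.baseline_start is None or self.baseline_end is None:
            raise ParameterError("baseline_start and baseline_end are required")
        start = pd.Timestamp(self.baseline_start).date()
        end = pd.Timestamp(self.baseline_end).date()
        if (pd.Timestamp(end) - pd.Timestamp(start)).days + 1 < 7:
            raise ParameterError("baseline window must span at least 7 days")

        long = _as_long(X, self.series_col, self.value_col)
        window = long[(long["date"] >= start) & (long["date"] <= end)]
        if self.zero_fill:
            cal = pd.date_range(start, end, freq="D")
            window = zero_fill_daily(window, cal)
        window = window.copy()
        window["weekday"] = pd.to_datetime(window["date"]).dt.dayofweek + 1

        prof = (window.groupby(["series_id", "weekday"])["value"]
                      .median().rename("baseline_value").reset_index())
        # a well-formed window covers all 7 weekdays for every series
        counts = prof.groupby("series_id")["weekday"].nunique()
        if (counts < 7).any():
            raise ParameterError("baseline window does not cover all 7 weekdays")
        bad = prof.loc[~(prof["baseline_value"] > 0), "series_id"].unique()
        self.baseline_ = prof
        self.non_rescalable_ = sorted(bad)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        long = _as_long(X, self.series_col, self.value_col)
        long["weekday"] = pd.to_datetime(long["date"]).dt.dayofweek + 1
        prof = self.baseline_[~self.baseline_["series_id"].isin(self.non_rescalable_)]
        merged = long.merge(prof, on=["series_id", "weekday"], how="inner")
        if self.non_rescalable_:
            logger.warning("excluding %d non-rescalable series (zero weekday median)",
                           len(self.non_rescalable_))
        out = merged[["series_id", "date"]].copy()
        out["pct"] = 100.0 * merged["value"] / merged["baseline_value"]
        out["pct_change"] = out["pct"] - 100.0
        return out.sort_values(["series_id", "date"]).reset_index(drop=True)


class SingleDayRescaler(BaseEstimator, TransformerMixin):
    """Rescale each series to percent of its value on one reference date
    (preserves weekly cycles; no weekday adjustment)."""

    def __init__(self, ref_date=None, series_col: str = "series_id",
                 value_col: str = "value"):
        self.ref_date = ref_date
        self.series_col = series_col
        self.value_col = value_col

    def fit(self, X: pd.DataFrame, y=None):
        if self.ref_date is None:
            raise ParameterError("ref_date is required")
        ref = pd.Timestamp(self.ref_date).date()
        long = _as_long(X, self.series_col, self.value_col)
        base = long[long["date"] == ref].set_index("series_id")["value"]
        missing = sorted(set(long["series_id"]) - set(base.index))
        if missing:
            raise ParameterError(f"series missing the reference date {ref}: {missing[:5]}")
        nonpos = sorted(base[~(base > 0)].index)
        if nonpos:
            raise ParameterError(f"zero/negative value on reference date for {nonpos[:5]}")
        self.reference_ = base
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        long = _as_long(X, self.series_col, self.value_col)
        base = long["series_id"].map(self.reference_)
        out = long[["series_id", "date"]].copy()
        out["pct"] = 100.0 * long["value"] / base
        out["pct_change"] = out["pct"] - 100.0
        return out.sort_values(["series_id", "date"]).reset_index(drop=True)


def weekday_median_baseline(daily: pd.DataFrame, baseline_start, baseline_end,
                            series_col: str = "series_id",
                            value_col: str = "value") -> tuple[pd.DataFrame, list]:
    """Per-series per-weekday medians over the baseline window.

    Returns (profile frame series_id, weekday, baseline_value,
    non-rescalable series ids)."""
    r = WeekdayMedianRescaler(baseline_start, baseline_end,
                              series_col=series_col, value_col=value_col).fit(daily)
    return r.baseline_, r.non_rescalable_


def rescale_to_baseline(daily: pd.DataFrame, profile: pd.DataFrame,
                        series_col: str = "series_id",
                        value_col: str = "value") -> tuple[pd.DataFrame, list]:
    """Apply a weekday-median profile; series with non-positive baselines are
    excluded with a report instead of raising. Returns (rescaled, excluded)."""
    long = _as_long(daily, series_col, value_col)
    long["weekday"] = pd.to_datetime(long["date"]).dt.dayofweek + 1
    bad = sorted(profile.loc[~(profile["baseline_value"] > 0), "series_id"].unique())
    good = profile[~profile["series_id"].isin(bad)]
    merged = long.merge(good, on=["series_id", "weekday"], how="inner")
    out = merged[["series_id", "date"]].copy()
    out["pct"] = 100.0 * merged["value"] / merged["baseline_value"]
    out["pct_change"] = out["pct"] - 100.0
    return out.sort_values(["series_id", "date"]).reset_index(drop=True), bad


def single_day_rescale(series: pd.DataFrame, ref_date,
                       series_col: str = "series_id",
                       value_col: str = "value") -> pd.DataFrame:
    """Functional wrapper over :class:`SingleDayRescaler`."""
    r = SingleDayRescaler(ref_date, series_col=series_col, value_col=value_col)
    return r.fit(series).transform(series)


def interpolate_missing(series: pd.DataFrame, series_col: str = "series_id",
                        value_col: str = "value") -> pd.DataFrame:
    """Fill interior missing dates of each series by linear interpolation.

    The series is completed to a daily calendar between its first and last
    observation; strictly interior gaps are interpolated linearly between
    the flanking observations, while leading/trailing gaps are left missing
    with a warning (no extrapolation).
    """
    long = _as_long(series, series_col, value_col)
    pieces = []
    for sid, grp in long.groupby("series_id"):
        grp = grp.dropna(subset=["value"])
        if len(grp) < 2:
            raise ParameterError(f"series '{sid}' needs >= 2 observed values")
        idx = pd.date_range(min(grp["date"]), max(grp["date"]), freq="D")
        s = grp.set_index(pd.to_datetime(grp["date"]))["value"].reindex(idx)
        filled = s.interpolate(method="linear", limit_area="inside")
        if filled.isna().any():
            logger.warning("series '%s': %d boundary gaps left missing",
                           sid, int(filled.isna().sum()))
        pieces.append(pd.DataFrame({
            series_col: sid, "date": [t.date() for t in idx], value_col: filled.to_numpy(),
        }))
    return pd.concat(pieces, ignore_index=True)


def regional_reference(daily: pd.DataFrame, included_cells, baseline_start,
                       baseline_end, method: str = "region-total",
                       series_col: str = "cell_id", value_col: str = "activity",
                       series_id: str = "region") -> pd.DataFrame:
    """The regional average activity series, rescaled to its own baseline.

    ``region-total`` (default) sums daily activity over the included cells
    and weekday-median-rescales the total — robust to low-count cells;
    ``mean-of-pcts`` averages the per-cell percentages instead.
    """
    cells = list(included_cells)
    if not cells:
        raise ParameterError("included_cells is empty")
    sub = daily[daily[series_col].isin(cells)]
    if method == "region-total":
        total = (sub.groupby("date")[value_col].sum().reset_index())
        total["series_id"] = series_id
        r = WeekdayMedianRescaler(baseline_start, baseline_end,
                                  value_col=value_col).fit(total)
        out = r.transform(total)
    elif method == "mean-of-pcts":
        r = WeekdayMedianRescaler(baseline_start, baseline_end,
                                  series_col=series_col, value_col=value_col).fit(sub)
        per_cell = r.transform(sub)
        out = per_cell.groupby("date")[["pct"]].mean().reset_index()
        out["series_id"] = series_id
        out["pct_change"] = out["pct"] - 100.0
        out = out[["series_id", "date", "pct", "pct_change"]]
    else:
        raise ParameterError(f"unknown reference method '{method}'")
    return out.reset_index(drop=True)
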