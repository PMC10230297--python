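"""Segmented (interrupted time-series) regression of activity deviations.

Each grid cell's percent-of-baseline activity is compared against the
regional reference series; the study period is partitioned into
policy-defined segments and, separately per geodemographic classification
scheme, an ordinary least squares regression of the cell-day deviations on
the full set of category x segment indicators (no intercept) estimates each
group's mean deviation — in percentage points — from the regional average
within each segment. A positive significant estimate means the group's
activity declined less than the region as a whole during that segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from mobigrid.errors import AlignmentError, ParameterError

NA_CATEGORY = "n/a"


@dataclass(frozen=True)
class SegmentDefinition:
    """A contiguous, inclusive date range of the study period."""

    segment_id: int
    name: str
    start_date: date
    end_date: date

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ParameterError(
                f"segment {self.segment_id}: end {self.end_date} before start {self.start_date}"
            )


def default_segments() -> list[SegmentDefinition]:
    """The five 2020 study segments: pre-pandemic baseline, precautionary
    behaviour, national lockdown, and the two phases of easing.

    The boundary day between the two easing phases (14 June) belongs to the
    second phase, so the segments partition the study window exactly.
    """
    return [
        SegmentDefinition(1, "baseline", date(2020, 1, 5), date(2020, 3, 8)),
        SegmentDefinition(2, "precaution", date(2020, 3, 9), date(2020, 3, 22)),
        SegmentDefinition(3, "lockdown", date(2020, 3, 23), date(2020, 5, 9)),
        SegmentDefinition(4, "easing_1", date(2020, 5, 10), date(2020, 6, 13)),
        SegmentDefinition(5, "easing_2", date(2020, 6, 14), date(2020, 7, 13)),
    ]


def validate_segments(segments: Sequence[SegmentDefinition]) -> list[SegmentDefinition]:
    segs = sorted(segments, key=lambda s: s.start_date)
    for a, b in zip(segs, segs[1:]):
        if b.start_date <= a.end_date:
            raise ParameterError(f"segments {a.segment_id} and {b.segment_id} overlap")
    return segs


def segment_of(dates, segments: Sequence[SegmentDefinition]) -> pd.Series:
    """Map each date to its segment_id; dates outside all segments get <NA>."""
    d = pd.to_datetime(pd.Series(dates)).dt.date
    out = pd.Series(pd.NA, index=d.index, dtype="Int64")
    for seg in segments:
        mask = (d >= seg.start_date) & (d <= seg.end_date)
        out[mask] = seg.segment_id
    return out


def build_response(rescaled_cells: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Cell-day deviations (percentage points) from the regional reference.

    Parameters
    ----------
    rescaled_cells : frame with columns ``series_id`` (cell id), ``date``, ``pct``
    reference : frame with columns ``date``, ``pct`` (one row per date)
    """
    ref = reference[["date", "pct"]].rename(columns={"pct": "ref_pct"})
    merged = rescaled_cells.merge(ref, on="date", how="left")
    if merged["ref_pct"].isna().any():
        missing = sorted(merged.loc[merged["ref_pct"].isna(), "date"].unique())[:5]
        raise AlignmentError(f"reference series missing dates, e.g. {missing}")
    out = merged[["series_id", "date"]].copy()
    out = out.rename(columns={"series_id": "cell_id"})
    out["dev_pp"] = merged["pct"] - merged["ref_pct"]
    return out


class SegmentedDeviationRegression(BaseEstimator):
    """No-intercept indicator OLS of cell-day deviations on category x segment.

    Because the design is a saturated set of group indicators without an
    intercept, each coefficient is exactly the mean deviation of its
    (category, segment) group; the OLS machinery supplies classical (or
    optionally heteroskedasticity-robust) standard errors and t-tests.

    Parameters
    ----------
    segments : list of SegmentDefinition, default the five study segments
    alpha : two-sided significance level for flagging estimates
    scheme : label recorded in the output tables (e.g. "LOAC", "IMD")
    unit : observation unit of the regression. "cell-segment" (default)
        first averages each cell's daily deviations within a segment, so
        the persistent per-cell component left by baseline estimation error
        enters each observation once and observations within a coefficient
        are independent across cells; "cell-day" regresses on raw cell-day
        deviations, whose within-cell serial correlation classical errors
        ignore.
    cov_type : "classical" homoskedastic errors (default), "hc1"
        heteroskedasticity-robust, or "cluster" (by grid cell; only
        meaningful with many cells per category).

    Attributes (after ``fit``)
    ----------
    estimates_ : frame scheme, category, segment_id, estimate_pp, std_err,
        p_value, significant — one row per category x segment; combinations
        with no observations carry NaN estimates (missing, not zero).
    fit_summaries_ : frame scheme, segment_id, adj_r2, n_obs from the
        segment-restricted subfits (categorical one-way model per segment).
    """

    def __init__(self, segments: list[SegmentDefinition] | None = None,
                 alpha: float = 0.05, scheme: str = "scheme",
                 unit: str = "cell-segment", cov_type: str = "classical"):
        self.segments = segments
        self.alpha = alpha
        self.scheme = scheme
        self.unit = unit
        self.cov_type = cov_type

    def _resolved_segments(self) -> list[SegmentDefinition]:
        return validate_segments(self.segments or default_segments())

    def fit(self, X: pd.DataFrame, y=None, classifications: pd.DataFrame | None = None):
        """Fit on a deviation table.

        Parameters
        ----------
        X : frame with columns ``cell_id``, ``date``, ``dev_pp``
        classifications : frame with columns ``cell_id``, ``category``;
            cells labelled "n/a" are excluded from the fit.
        """
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if classifications is None:
            raise ParameterError("classifications frame is required")
        segs = self._resolved_segments()

        cls = classifications[["cell_id", "category"]].copy()
        cls["category"] = cls["category"].astype(str)
        cls = cls[cls["category"] != NA_CATEGORY]
        df = X.merge(cls, on="cell_id", how="inner")
        df["segment_id"] = segment_of(df["date"], segs)
        df = df.dropna(subset=["segment_id", "dev_pp"])
        if df.empty:
            raise ParameterError("no classified observations fall inside the segments")
        df["segment_id"] = df["segment_id"].astype(int)

        if self.unit == "cell-segment":
            df = (df.groupby(["cell_id", "category", "segment_id"])["dev_pp"]
                    .mean().reset_index())
        elif self.unit != "cell-day":
            raise ParameterError(f"unknown unit '{self.unit}'")

        categories = sorted(df["category"].unique())
        group = df["category"] + "|" + df["segment_id"].astype(str)
        design = pd.get_dummies(group, dtype=float)
        model = sm.OLS(df["dev_pp"].to_numpy(), design.to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.cov_type == "cluster":
                groups = df["cell_id"].astype("category").cat.codes.to_numpy()
                res = model.fit(cov_type="cluster", cov_kwds={"groups": groups},
                                use_t=True)
            elif self.cov_type == "hc1":
                res = model.fit(cov_type="HC1")
            elif self.cov_type == "classical":
                res = model.fit()
            else:
                raise ParameterError(f"unknown cov_type '{self.cov_type}'")

        with np.errstate(invalid="ignore", divide="ignore"):
            ci = res.conf_int(alpha=self.alpha)
        coef = pd.DataFrame({
            "group": design.columns,
            "estimate_pp": res.params,
            "std_err": res.bse,
            "p_value": res.pvalues,
            "ci_low": ci[:, 0] if isinstance(ci, np.ndarray) else np.asarray(ci)[:, 0],
            "ci_high": ci[:, 1] if isinstance(ci, np.ndarray) else np.asarray(ci)[:, 1],
        })
        parts = coef["group"].str.rsplit("|", n=1, expand=True)
        coef["category"] = parts[0]
        coef["segment_id"] = parts[1].astype(int)

        full = pd.MultiIndex.from_product(
            [categories, [s.segment_id for s in segs]], names=["category", "segment_id"]
        ).to_frame(index=False)
        est = full.merge(coef.drop(columns="group"), on=["category", "segment_id"], how="left")
        est.insert(0, "scheme", self.scheme)
        est["significant"] = pd.array(est["p_value"] < self.alpha, dtype="boolean")
        est.loc[est["p_value"].isna(), "significant"] = pd.NA
        self.estimates_ = est.sort_values(["category", "segment_id"]).reset_index(drop=True)

        summaries = []
        for seg in segs:
            sub = df[df["segment_id"] == seg.segment_id]
            if sub.empty:
                summaries.append((self.scheme, seg.segment_id, np.nan, 0))
                continue
            dm = pd.get_dummies(sub["category"], dtype=float)
            subres = sm.OLS(sub["dev_pp"].to_numpy(), dm.to_numpy()).fit()
            # centred (intercept-equivalent) adjusted R^2: share of variation
            # in deviations explained by group membership within the segment
            yv = sub["dev_pp"].to_numpy()
            sst = float(((yv - yv.mean()) ** 2).sum())
            ssr = float((subres.resid**2).sum())
            n, p = len(yv), dm.shape[1]
            if sst > 0 and n > p:
                r2 = 1.0 - ssr / sst
                adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
            else:
                adj = np.nan
            summaries.append((self.scheme, seg.segment_id, adj, n))
        self.fit_summaries_ = pd.DataFrame(
            summaries, columns=["scheme", "segment_id", "adj_r2", "n_obs"]
        )
        self.n_obs_ = len(df)
        self.categories_ = categories
        return self

    def predict(self, X: pd.DataFrame, classifications: pd.DataFrame | None = None) -> np.ndarray:
        """Fitted group-mean deviation for each (cell, date) row."""
        if classifications is None:
            raise ParameterError("classifications frame is required")
        segs = self._resolved_segments()
        df = X.merge(classifications[["cell_id", "category"]], on="cell_id", how="left")
        df["segment_id"] = segment_of(df["date"], segs)
        est = self.estimates_.set_index(["category", "segment_id"])["estimate_pp"]
        keys = pd.MultiIndex.from_frame(df[["category", "segment_id"]])
        return est.reindex(keys).to_numpy()


def fit_scheme(deviations: pd.DataFrame, classifications: pd.DataFrame,
               segments: list[SegmentDefinition] | None = None,
               alpha: float = 0.05, scheme: str = "scheme",
               unit: str = "cell-segment",
               cov_type: str = "classical") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper around :class:`SegmentedDeviationRegression`."""
    model = SegmentedDeviationRegression(
        segments=segments, alpha=alpha, scheme=scheme, unit=unit, cov_type=cov_type
    ).fit(deviations, classifications=classifications)
    return model.estimates_, model.fit_summaries_


def significance_map(estimates: pd.DataFrame, classifications: pd.DataFrame,
                     segment_id: int) -> pd.DataFrame:
    """Label each cell by the sign/significance of its category's estimate.

    Returns a frame cell_id, category, label with label one of
    ``sig_positive``, ``sig_negative``, ``not_significant``, ``n/a``.
    """
    seg = estimates[estimates["segment_id"] == segment_id]
    if seg.empty:
        known = sorted(estimates["segment_id"].unique())
        raise ParameterError(f"unknown segment {segment_id}; have {known}")

    def _label(row):
        if pd.isna(row["estimate_pp"]) or pd.isna(row["p_value"]):
            return NA_CATEGORY
        if not row["significant"]:
            return "not_significant"
        return "sig_positive" if row["estimate_pp"] > 0 else "sig_negative"

    labels = seg.assign(label=seg.apply(_label, axis=1))[["category", "label"]]
    out = classifications[["cell_id", "category"]].merge(labels, on="category", how="left")
    out.loc[out["category"] == NA_CATEGORY, "label"] = NA_CATEGORY
    out["label"] = out["label"].fillna(NA_CATEGORY)
    return out
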