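"""Reading, validation and normalisation of pings, zone layers and
external mobility-report series.

Every reader returns validated, planar-metre records plus an explicit
reject report; malformed rows are counted and reported, never silently
dropped. Accepted + rejected always equals the input row count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from mobigrid.errors import FormatError
from mobigrid.geo import LocalProjection, read_geojson
from mobigrid.synth import Zone

logger = logging.getLogger(__name__)

PING_COLUMNS = ["device_id", "app_id", "timestamp", "x_m", "y_m", "accuracy_m"]
GEO_COLUMNS = ["device_id", "app_id", "timestamp", "lon", "lat", "accuracy_m"]


@dataclass
class RejectReport:
    """Per-reason counts of rows rejected during validation."""

    input_rows: int = 0
    accepted: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def rejected(self) -> int:
        return self.input_rows - self.accepted

    def to_dict(self) -> dict:
        return {"input_rows": self.input_rows, "accepted": self.accepted,
                "rejected": self.rejected, "reasons": dict(self.reasons)}


def read_pings(path, crs_spec: dict | None = None,
               study_window: tuple | None = None) -> tuple[pd.DataFrame, RejectReport]:
    """Read a ping CSV into validated planar records.

    Parameters
    ----------
    path : CSV with columns device_id, app_id, timestamp (ISO-8601), then
        either planar x_m, y_m or geographic lon, lat, plus accuracy_m.
    crs_spec : for geographic input, ``{"lon0": ..., "lat0": ...}`` anchoring
        the local east-north projection; ignored for planar input.
    study_window : optional (start, end) dates; rows outside are rejected.

    Returns (frame with PING_COLUMNS, reject report).
    """
    raw = pd.read_csv(path, dtype={"device_id": str, "app_id": str})
    geographic = {"lon", "lat"}.issubset(raw.columns)
    required = GEO_COLUMNS if geographic else PING_COLUMNS
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"ping table missing required column '{col}'")
    if geographic and crs_spec is None:
        raise FormatError("geographic coordinates require a crs_spec with lon0/lat0")

    report = RejectReport(input_rows=len(raw))
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    ok = ts.notna()
    _count(report, "unparseable_timestamp", ~ok)

    for col in ("x_m", "y_m", "accuracy_m") if not geographic else ("lon", "lat", "accuracy_m"):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & ok
        _count(report, f"non_numeric_{col}", bad)
        ok &= numeric.notna()
        raw[col] = numeric

    bad_acc = ok & (raw["accuracy_m"] < 0)
    _count(report, "negative_accuracy", bad_acc)
    ok &= ~bad_acc

    if study_window is not None:
        lo, hi = (pd.Timestamp(t, tz="UTC") for t in study_window)
        outside = ok & ~((ts >= lo) & (ts <= hi + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)))
        _count(report, "outside_study_window", outside)
        ok &= ~outside

    df = raw[ok].copy()
    df["timestamp"] = ts[ok]
    if geographic:
        proj = LocalProjection(lon0=float(crs_spec["lon0"]), lat0=float(crs_spec["lat0"]))
        x, y = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
        df["x_m"], df["y_m"] = x, y
        df = df.drop(columns=["lon", "lat"])
    report.accepted = len(df)
    if report.rejected:
        logger.warning("read_pings: rejected %d/%d rows: %s",
                       report.rejected, report.input_rows, report.reasons)
    return df[PING_COLUMNS].reset_index(drop=True), report


def _count(report: RejectReport, reason: str, mask) -> None:
    n = int(np.asarray(mask).sum())
    if n:
        report.reasons[reason] = report.reasons.get(reason, 0) + n


def write_pings(df: pd.DataFrame, path) -> None:
    """Write pings as CSV with ISO-8601 UTC timestamps (round-trips with
    :func:`read_pings`)."""
    out = df[PING_COLUMNS].copy()
    ts = pd.to_datetime(out["timestamp"], utc=True)
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"
    out.to_csv(path, index=False, float_format="%.6f")


def read_zone_layer(polygon_path, centroid_path) -> tuple[list[Zone], list[str]]:
    """Assemble zones from polygon and centroid FeatureCollections.

    Every centroid must reference an existing zone_id and every zone_id must
    be unique; zones without a centroid are retained but flagged — they get
    no classification linkage downstream (category handling marks them n/a).
    A centroid falling outside its own polygon is tolerated with a warning
    (real population-weighted centroids can fall outside concave units).

    Returns (zones, zone_ids_without_centroid).
    """
    polys = read_geojson(polygon_path)
    cents = read_geojson(centroid_path)

    seen: dict[str, tuple[Polygon, dict]] = {}
    for geom, props in polys:
        zid = props.get("zone_id")
        if zid is None:
            raise FormatError("polygon feature missing zone_id property")
        if zid in seen:
            raise FormatError(f"duplicate zone_id '{zid}' in polygon layer")
        seen[zid] = (geom, props)

    centroids: dict[str, Point] = {}
    for geom, props in cents:
        zid = props.get("zone_id")
        if zid not in seen:
            raise FormatError(f"centroid references unknown zone_id '{zid}'")
        if zid in centroids:
            raise FormatError(f"duplicate centroid for zone_id '{zid}'")
        centroids[zid] = geom

    zones: list[Zone] = []
    missing: list[str] = []
    for zid, (geom, props) in seen.items():
        pt = centroids.get(zid)
        if pt is None:
            missing.append(zid)
            pt = Point(float("nan"), float("nan"))
        elif not geom.contains(pt) and not geom.touches(pt):
            logger.warning("centroid of zone %s falls outside its polygon", zid)
        zones.append(Zone(
            zone_id=zid, polygon=geom, category=str(props.get("category", "n/a")),
            weight=float(props.get("weight", 0.0)), centroid=pt,
        ))
    return zones, sorted(missing)


def read_external_series(path) -> pd.DataFrame:
    """Read an external mobility-report CSV (source,date,value) into a long
    frame; dates must be strictly increasing within each source."""
    df = pd.read_csv(path)
    for col in ("source", "date", "value"):
        if col not in df.columns:
            raise FormatError(f"external series missing required column '{col}'")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["value"] = pd.to_numeric(df["value"])
    for src, grp in df.groupby("source"):
        d = pd.Series(grp["date"].to_numpy())
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise FormatError(f"dates for source '{src}' are not strictly increasing")
    return df.reset_index(drop=True)
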