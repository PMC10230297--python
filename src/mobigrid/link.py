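"""Linking geodemographic classifications to grid cells.

Areal units (output areas, workplace zones, ...) rarely nest inside 1 km
grid cells, so each unit is represented by its population-weighted centroid
and assigned — with its weight (residents or workplaces) — to the single
cell containing that point; the cell then takes the category with the
largest summed weight. Retail-centre typologies are not population-based,
so they are assigned by largest polygon-cell overlap area instead.

Two diagnostics evaluate the linkage: the correlation between cell weights
and pre-lockdown activity, and the discrepancy between category areal
shares before and after gridding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from shapely.validation import explain_validity

from mobigrid.errors import GeometryError, ParameterError
from mobigrid.geo import cell_polygon, point_cell_id
from mobigrid.segreg import NA_CATEGORY
from mobigrid.synth import Zone

logger = logging.getLogger(__name__)


def centroids_to_cells(zones: list[Zone], origin: tuple[float, float] = (0.0, 0.0),
                       cell_size_m: float = 1000.0,
                       bounds: tuple[float, float, float, float] | None = None
                       ) -> pd.DataFrame:
    """Point-in-cell assignment of zone centroids on the half-open grid.

    Zones without a centroid (NaN coordinates) stay unmapped; with explicit
    grid ``bounds`` (minx, miny, maxx, maxy), centroids outside the extent
    are unmapped with a warning.
    """
    rows = []
    for z in zones:
        x, y = z.centroid.x, z.centroid.y
        if np.isnan(x) or np.isnan(y):
            continue
        if bounds is not None and not (bounds[0] <= x < bounds[2]
                                       and bounds[1] <= y < bounds[3]):
            logger.warning("centroid of zone %s outside grid extent; unmapped", z.zone_id)
            continue
        rows.append((z.zone_id, str(point_cell_id(x, y, origin, cell_size_m))))
    return pd.DataFrame(rows, columns=["zone_id", "cell_id"])


def dominant_category(mapping: pd.DataFrame, zones: list[Zone], scheme: str,
                      cells: list[str] | None = None) -> pd.DataFrame:
    """Assign each cell the category with the largest summed centroid weight.

    Ties break to the lexicographically smallest category. Cells listed in
    ``cells`` that receive no centroid are emitted as "n/a" with zero
    weights, matching how unmatched cells are carried through the analysis.

    Returns a frame cell_id, scheme, category, winning_weight, total_weight.
    """
    zinfo = pd.DataFrame(
        [(z.zone_id, z.category, z.weight) for z in zones],
        columns=["zone_id", "category", "weight"])
    if (zinfo["weight"] < 0).any():
        raise ParameterError("zone weights must be non-negative")
    df = mapping.merge(zinfo, on="zone_id", how="inner")
    by_cat = (df.groupby(["cell_id", "category"])["weight"].sum().reset_index())
    by_cat = by_cat.sort_values(["cell_id", "weight", "category"],
                                ascending=[True, False, True], kind="stable")
    win = by_cat.groupby("cell_id").first().reset_index()
    tot = by_cat.groupby("cell_id")["weight"].sum().rename("total_weight")
    out = win.merge(tot, on="cell_id")
    out = out.rename(columns={"category": "category", "weight": "winning_weight"})
    out.insert(1, "scheme", scheme)
    if cells is not None:
        missing = sorted(set(cells) - set(out["cell_id"]))
        if missing:
            out = pd.concat([out, pd.DataFrame({
                "cell_id": missing, "scheme": scheme, "category": NA_CATEGORY,
                "winning_weight": 0.0, "total_weight": 0.0,
            })], ignore_index=True)
    return out.sort_values("cell_id").reset_index(drop=True)


def area_overlap_category(retail_zones: list[Zone], cells: list[str], scheme: str,
                          origin: tuple[float, float] = (0.0, 0.0),
                          cell_size_m: float = 1000.0) -> pd.DataFrame:
    """Assign each cell the typology with the largest polygon-overlap area.

    Cells with zero overlap get "n/a". ``winning_weight``/``total_weight``
    hold overlap areas in m^2.
    """
    for z in retail_zones:
        if not z.polygon.is_valid:
            raise GeometryError(
                f"invalid geometry for feature '{z.zone_id}': {explain_validity(z.polygon)}")
    rows = []
    for cid in cells:
        cpoly = cell_polygon(cid, origin, cell_size_m)
        areas: dict[str, float] = {}
        for z in retail_zones:
            a = cpoly.intersection(z.polygon).area
            if a > 0:
                areas[z.category] = areas.get(z.category, 0.0) + a
        if areas:
            cat = min(areas, key=lambda c: (-areas[c], c))
            rows.append((cid, scheme, cat, areas[cat], sum(areas.values())))
        else:
            rows.append((cid, scheme, NA_CATEGORY, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["cell_id", "scheme", "category",
                                       "winning_weight", "total_weight"])


def weight_activity_correlation(cell_classifications: pd.DataFrame,
                                daily: pd.DataFrame, window_start, window_end
                                ) -> pd.DataFrame:
    """Pearson correlation between cell total weights and mean daily
    activity over the pre-lockdown window, per scheme.

    Degenerate (constant) weights yield an undefined correlation, reported
    as NaN rather than raising. Returns a frame scheme, r, p_value, n_cells.
    """
    start = pd.Timestamp(window_start).date()
    end = pd.Timestamp(window_end).date()
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.date
    window = d[(d["date"] >= start) & (d["date"] <= end)]
    mean_act = window.groupby("cell_id")["activity"].mean().rename("mean_activity")

    rows = []
    for scheme, grp in cell_classifications.groupby("scheme"):
        sub = (grp[grp["category"] != NA_CATEGORY]
               .merge(mean_act, on="cell_id", how="inner"))
        if len(sub) < 3:
            raise ParameterError(f"scheme '{scheme}': need >= 3 cells, have {len(sub)}")
        w = sub["total_weight"].to_numpy(dtype=float)
        a = sub["mean_activity"].to_numpy(dtype=float)
        if np.ptp(w) == 0 or np.ptp(a) == 0:
            rows.append((scheme, np.nan, np.nan, len(sub)))
        else:
            r, p = stats.pearsonr(w, a)
            rows.append((scheme, float(r), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["scheme", "r", "p_value", "n_cells"])


def areal_distribution_check(cell_classifications: pd.DataFrame,
                             zones: list[Zone], scheme: str,
                             cell_area_m2: float = 1_000_000.0) -> pd.DataFrame:
    """Per-category discrepancy between gridded and original areal shares.

    For each category: the share of total assigned cell area it receives
    minus the share of original zone area it holds, in signed percentage
    points. Dominant-category gridding over-represents categories whose
    small, heavy units sit inside larger zones of other categories.
    """
    assigned = cell_classifications[
        (cell_classifications["scheme"] == scheme)
        & (cell_classifications["category"] != NA_CATEGORY)]
    cell_counts = assigned.groupby("category").size()
    cell_share = 100.0 * cell_counts * cell_area_m2 / (cell_counts.sum() * cell_area_m2)

    zarea = pd.Series({z.zone_id: z.polygon.area for z in zones})
    zcat = pd.Series({z.zone_id: z.category for z in zones})
    zone_share = 100.0 * zarea.groupby(zcat).sum() / zarea.sum()

    cats = sorted(set(cell_share.index) | set(zone_share.index))
    out = pd.DataFrame({
        "category": cats,
        "cell_share_pct": [float(cell_share.get(c, 0.0)) for c in cats],
        "zone_share_pct": [float(zone_share.get(c, 0.0)) for c in cats],
    })
    out["delta_pp"] = out["cell_share_pct"] - out["zone_share_pct"]
    return out
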