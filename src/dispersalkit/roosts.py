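"""Communal-roost identification from night-adjacent positions.

Non-breeding red kites roost communally; a roost close to the natal nest can
delay the scored departure, so each nest's distance to the nearest roost is
a control covariate.  Roosts are found per year by (1) filtering tracks to
night-adjacent positions in July–September inside the buffered study area,
(2) scoring each position's revisitation rate — the number of entry events
of the pooled night trajectory into a 50 m disc around it, (3) keeping the
top 5% most-revisited positions, and (4) k-means clustering those into k=10
roost centroids.

Hourly duty cycles record no true night fixes, so "night position" is
proxied by the last fix of each UTC day and the first fix of the following
day (``night_rule="day_boundary"``); a clock-window rule (19:00–05:00 UTC)
is available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans

from .geometry import LocalProjection, geodesic_distance_m

__all__ = [
    "RoostParams",
    "RoostSet",
    "filter_night_positions",
    "revisit_counts",
    "select_top",
    "cluster_roosts",
    "nearest_roost_distance",
    "find_roosts",
]


@dataclass(frozen=True)
class RoostParams:
    revisit_radius_m: float = 50.0
    top_fraction: float = 0.05
    k_clusters: int = 10
    season_months: tuple[int, ...] = (7, 8, 9)
    study_buffer_m: float = 10_000.0
    night_rule: str = "day_boundary"  # or "clock_window"
    night_window_utc: tuple[int, int] = (19, 5)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.k_clusters < 1 or self.revisit_radius_m <= 0:
            raise ValueError("k_clusters >= 1 and revisit_radius_m > 0 required")
        if self.night_rule not in ("day_boundary", "clock_window"):
            raise ValueError(f"unknown night_rule {self.night_rule!r}")


@dataclass
class RoostSet:
    """Per-year roost centroids with memberships and revisitation scores."""

    year: int
    centroids: pd.DataFrame  # columns: cluster, lon, lat, n_members
    members: pd.DataFrame    # columns: individual_id, t, lon, lat, score, cluster
    params: RoostParams | None = None

    def __len__(self) -> int:
        return len(self.centroids)


def filter_night_positions(
    fixes: pd.DataFrame,
    study_polygon: Polygon,
    params: RoostParams = RoostParams(),
) -> pd.DataFrame:
    """Night-adjacent fixes in season inside the buffered study polygon.

    ``fixes`` is a canonical fix frame (individual_id, t, lon, lat); the
    polygon is a lon/lat ring.  Buffering happens in the local metric
    projection so ``study_buffer_m`` is an honest distance.
    """
    df = fixes[fixes["t"].dt.month.isin(params.season_months)]
    if len(df) == 0:
        warnings.warn("no fixes in roosting season; roost detection will be empty")
        return df.copy()

    proj = LocalProjection(*_polygon_origin(study_polygon))
    px, py = proj.forward(np.array(study_polygon.exterior.coords)[:, 0],
                          np.array(study_polygon.exterior.coords)[:, 1])
    poly_m = Polygon(np.column_stack([px, py])).buffer(params.study_buffer_m)
    fx, fy = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = np.array([poly_m.contains(Point(x, y)) or poly_m.touches(Point(x, y))
                       for x, y in zip(fx, fy)])
    df = df[inside]

    if params.night_rule == "clock_window":
        h = df["t"].dt.hour
        lo, hi = params.night_window_utc
        mask = (h >= lo) | (h < hi) if lo > hi else (h >= lo) & (h < hi)
        night = df[mask]
    else:
        day = df["t"].dt.floor("D")
        grp = df.groupby([df["individual_id"], day])["t"]
        last_of_day = grp.transform("max") == df["t"]
        first_of_day = grp.transform("min") == df["t"]
        night = df[last_of_day | first_of_day]
    if len(night) == 0:
        warnings.warn("night-position filter removed all fixes")
    return night.sort_values(["individual_id", "t"]).reset_index(drop=True)


def _polygon_origin(polygon: Polygon) -> tuple[float, float]:
    c = polygon.centroid
    return float(c.x), float(c.y)


def revisit_counts(
    focal_xy: np.ndarray, track_xy_by_id: dict[str, np.ndarray], radius_m: float
) -> np.ndarray:
    """Entry-event counts into the disc around each focal point.

    For every focal point, counts transitions from outside to inside the
    disc of ``radius_m`` across all individuals' ordered night trajectories;
    a trajectory that starts inside contributes one entry.  This is the
    recursion/revisitation statistic of movement-trajectory analysis.
    """
    n = len(focal_xy)
    counts = np.zeros(n, dtype=int)
    if n == 0:
        return counts
    for xy in track_xy_by_id.values():
        if len(xy) == 0:
            continue
        # (n_focal, n_fix) inside mask, chunked over focal points
        chunk = max(1, int(4e6 // max(len(xy), 1)))
        for i0 in range(0, n, chunk):
            f = focal_xy[i0 : i0 + chunk]
            d2 = (f[:, 0, None] - xy[None, :, 0]) ** 2 + (f[:, 1, None] - xy[None, :, 1]) ** 2
            inside = d2 <= radius_m**2
            entries = inside[:, 0].astype(int) + np.sum(inside[:, 1:] & ~inside[:, :-1], axis=1)
            counts[i0 : i0 + chunk] += entries
    return counts


def select_top(points: pd.DataFrame, counts: np.ndarray, top_fraction: float) -> pd.DataFrame:
    """Most-revisited positions: at least ceil(top_fraction*n), ties at the cutoff kept."""
    n = len(points)
    if n == 0:
        return points.assign(score=pd.Series(dtype=int))
    m = math.ceil(top_fraction * n)
    cutoff = np.sort(counts)[::-1][m - 1]
    sel = counts >= cutoff
    out = points[sel].copy()
    out["score"] = counts[sel]
    return out.reset_index(drop=True)


def cluster_roosts(
    selected: pd.DataFrame,
    params: RoostParams,
    projection: LocalProjection,
    year: int,
) -> RoostSet:
    """k-means the selected positions (in projected metres) into roost centroids."""
    if len(selected) == 0:
        empty = pd.DataFrame(columns=["cluster", "lon", "lat", "n_members"])
        return RoostSet(year=year, centroids=empty, members=selected.copy(), params=params)
    k = params.k_clusters
    if len(selected) < k:
        warnings.warn(f"only {len(selected)} selected positions; reducing k from {k}")
        k = len(selected)
    x, y = projection.forward(selected["lon"].to_numpy(), selected["lat"].to_numpy())
    km = KMeans(n_clusters=k, n_init=25, random_state=params.seed).fit(np.column_stack([x, y]))
    lab = km.labels_
    clon, clat = projection.inverse(km.cluster_centers_[:, 0], km.cluster_centers_[:, 1])
    centroids = pd.DataFrame(
        {
            "cluster": np.arange(k),
            "lon": clon,
            "lat": clat,
            "n_members": np.bincount(lab, minlength=k),
        }
    )
    members = selected.copy()
    members["cluster"] = lab
    return RoostSet(year=year, centroids=centroids, members=members, params=params)


def find_roosts(
    fixes: pd.DataFrame,
    study_polygon: Polygon,
    year: int,
    params: RoostParams = RoostParams(),
) -> RoostSet:
    """Full per-year pipeline: night filter -> revisit scores -> top 5% -> k-means."""
    yfix = fixes[fixes["t"].dt.year == year]
    night = filter_night_positions(yfix, study_polygon, params)
    proj = LocalProjection(*_polygon_origin(study_polygon))
    if len(night) == 0:
        return cluster_roosts(night, params, proj, year)
    x, y = proj.forward(night["lon"].to_numpy(), night["lat"].to_numpy())
    xy = np.column_stack([x, y])
    by_id = {
        iid: xy[np.flatnonzero((night["individual_id"] == iid).to_numpy())]
        for iid in night["individual_id"].unique()
    }
    counts = revisit_counts(xy, by_id, params.revisit_radius_m)
    selected = select_top(night, counts, params.top_fraction)
    return cluster_roosts(selected, params, proj, year)


def nearest_roost_distance(nest: tuple[float, float], roostset: RoostSet) -> float:
    """Geodesic metres from a nest (lon, lat) to the closest roost centroid."""
    if len(roostset) == 0:
        warnings.warn(f"no roosts for year {roostset.year}; distance undefined")
        return float("nan")
    d = geodesic_distance_m(
        roostset.centroids["lon"].to_numpy(),
        roostset.centroids["lat"].to_numpy(),
        nest[0],
        nest[1],
    )
    return float(np.min(d))
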