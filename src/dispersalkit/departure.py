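"""Departure-to-dispersal detection by a spatio-temporal geofence rule.

A juvenile is scored as departed at the first time it stays *continuously*
outside a nest-centred radius (default 2 km) for longer than a temporal
threshold (default 2 days).  Continuity is judged on the fix sequence: a
maximal run of consecutive fixes all beyond the radius is one absence, its
duration the time from the run's first to its last fix.  Overnight
duty-cycle gaps flanked by outside fixes therefore count as outside time,
and a single inside fix terminates a run.

The departure timestamp is anchored at the first fix of the qualifying run
(``anchor="first_outside"``); the midpoint of the boundary-crossing gap is
available as a config switch.  Ages are continuous days since hatching; the
post-fledging dependence period (PFDP) subtracts a fixed fledging age
(default 55 d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import geodesic_distance_m

DAY = pd.Timedelta(days=1)

#: fate / status labels
DEPARTED = "departed"
CENSORED = "censored_no_departure"
EXCLUDED_FAILED = "excluded_failed"
EXCLUDED_MIGRATED = "excluded_migrated"

_KNOWN_FATES = {"included", "failed", "migrated"}

__all__ = [
    "DepartureParams",
    "DepartureResult",
    "outside_runs",
    "detect_departure",
    "threshold_sensitivity",
    "count_full_day_returns",
    "migration_flag",
    "apply_exclusions",
]


@dataclass(frozen=True)
class DepartureParams:
    radius_m: float = 2000.0
    min_outside_days: float = 2.0
    validation_thresholds_days: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 9.0)
    fledging_age_days: float = 55.0
    #: "first_outside" anchors departure at the first fix of the qualifying
    #: run; "gap_midpoint" at the midpoint between the last inside fix and
    #: the first outside fix.
    anchor: str = "first_outside"

    def __post_init__(self):
        if self.radius_m <= 0 or self.min_outside_days <= 0 or self.fledging_age_days <= 0:
            raise ValueError("radius_m, min_outside_days and fledging_age_days must be > 0")
        if self.anchor not in ("first_outside", "gap_midpoint"):
            raise ValueError(f"unknown anchor rule {self.anchor!r}")


@dataclass
class DepartureResult:
    individual_id: str
    status: str
    departure_t: pd.Timestamp | None
    departure_age_days: float | None
    pfdp_days: float | None
    params: DepartureParams
    threshold_ages: dict[float, float | None] = field(default_factory=dict)


def _distances_from_nest(track: pd.DataFrame, nest: tuple[float, float]) -> np.ndarray:
    return np.asarray(
        geodesic_distance_m(track["lon"].to_numpy(), track["lat"].to_numpy(), nest[0], nest[1])
    )


def outside_runs(
    track: pd.DataFrame, nest: tuple[float, float], radius_m: float
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal runs of consecutive fixes strictly beyond ``radius_m`` of the nest.

    Returns ``(start_t, end_t)`` per run; a single outside fix yields a
    zero-duration run.  Empty track -> empty list.
    """
    if len(track) == 0:
        return []
    outside = _distances_from_nest(track, nest) > radius_m
    t = track["t"].to_numpy()
    runs: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    # boundaries of True-runs in the boolean mask
    padded = np.concatenate(([False], outside, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    for s, e in zip(starts, ends):
        runs.append((pd.Timestamp(t[s]), pd.Timestamp(t[e])))
    return runs


def _first_qualifying_run(runs, min_outside_days: float, track_end: pd.Timestamp):
    """First run strictly longer than the threshold.

    The final run is open-ended only in the sense that tracking stopped; its
    observed duration still ends at its last fix, so a bird whose record ends
    mid-absence is censored unless the observed absence already exceeds the
    threshold.
    """
    thr = pd.Timedelta(days=min_outside_days)
    for start, end in runs:
        if end - start > thr:
            return start, end
    return None


def detect_departure(
    track: pd.DataFrame,
    nest: tuple[float, float],
    hatching_date: pd.Timestamp,
    params: DepartureParams = DepartureParams(),
    individual_id: str | None = None,
) -> DepartureResult:
    """Score the departure of one juvenile from its fix sequence.

    ``hatching_date`` may be a date or timestamp; ages are continuous days
    from it to the departure anchor.
    """
    hatch = pd.Timestamp(hatching_date)
    if hatch.tzinfo is None:
        hatch = hatch.tz_localize("UTC")
    iid = individual_id or (str(track["individual_id"].iloc[0]) if len(track) else "?")
    if len(track):
        first_fix = pd.Timestamp(track["t"].iloc[0])
        if first_fix - hatch > pd.Timedelta(days=365):
            raise ValueError(
                f"{iid}: hatching date {hatch.date()} precedes first fix by more than a year"
            )

    runs = outside_runs(track, nest, params.radius_m)
    hit = _first_qualifying_run(runs, params.min_outside_days, None)
    if hit is None:
        return DepartureResult(iid, CENSORED, None, None, None, params)

    start, _end = hit
    departure_t = start
    if params.anchor == "gap_midpoint":
        prev = track.loc[track["t"] < start, "t"]
        if len(prev):
            departure_t = prev.iloc[-1] + (start - prev.iloc[-1]) / 2
    age = (departure_t - hatch) / DAY
    return DepartureResult(
        iid,
        DEPARTED,
        departure_t,
        float(age),
        float(age - params.fledging_age_days),
        params,
    )


def threshold_sensitivity(
    track: pd.DataFrame,
    nest: tuple[float, float],
    hatching_date: pd.Timestamp,
    params: DepartureParams = DepartureParams(),
) -> pd.DataFrame:
    """Departure age under each validation threshold.

    One row per threshold; ages are non-decreasing in the threshold because
    a longer absence requirement can only postpone (or censor) the
    qualifying run.
    """
    rows = []
    for thr in sorted(params.validation_thresholds_days):
        p = DepartureParams(
            radius_m=params.radius_m,
            min_outside_days=thr,
            validation_thresholds_days=params.validation_thresholds_days,
            fledging_age_days=params.fledging_age_days,
            anchor=params.anchor,
        )
        res = detect_departure(track, nest, hatching_date, p)
        rows.append(
            {
                "threshold_days": thr,
                "status": res.status,
                "departure_age_days": res.departure_age_days,
            }
        )
    return pd.DataFrame(rows)


def count_full_day_returns(
    track: pd.DataFrame,
    nest: tuple[float, float],
    radius_m: float,
    departure_t: pd.Timestamp,
) -> int:
    """Number of post-departure UTC calendar days spent entirely inside the radius."""
    post = track[track["t"] > departure_t]
    if len(post) == 0:
        return 0
    inside = _distances_from_nest(post, nest) <= radius_m
    days = post["t"].dt.floor("D")
    per_day = pd.Series(inside).groupby(days.to_numpy()).all()
    return int(per_day.sum())


def migration_flag(
    track: pd.DataFrame,
    nest: tuple[float, float],
    params: DepartureParams = DepartureParams(),
    migration_radius_m: float = 50_000.0,
) -> bool:
    """Heuristic pre-departure-migration flag.

    True when the bird's first displacement beyond ``migration_radius_m``
    from the nest has no subsequent return inside that radius and occurs
    before any nest-radius absence has lasted longer than the departure
    threshold — i.e. the bird left on migration without a prior sustained
    local departure.  Used only when metadata carries no fate flag.
    """
    if len(track) == 0:
        return False
    d = _distances_from_nest(track, nest)
    far = d > migration_radius_m
    if not far.any():
        return False
    i_far = int(np.argmax(far))
    if np.any(d[i_far:] <= migration_radius_m):
        return False  # came back: not a one-way migration
    t_far = pd.Timestamp(track["t"].iloc[i_far])
    # time at which an absence first *qualifies* = run start + threshold
    for start, end in outside_runs(track, nest, params.radius_m):
        qualify_t = start + pd.Timedelta(days=params.min_outside_days)
        if end - start > pd.Timedelta(days=params.min_outside_days) and qualify_t < t_far:
            return False
    return True


def apply_exclusions(roster: pd.DataFrame, results: dict[str, DepartureResult] | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysis-set filters to a tagging roster.

    ``roster`` needs columns ``individual_id`` and ``fate`` with values in
    {included, failed, migrated}: birds that died or whose transmitter
    stopped before departure (``failed``) and birds that started migration
    without departing (``migrated``) are excluded.  When per-bird detector
    ``results`` are supplied, individuals without a scored departure are
    additionally dropped as censored.

    Returns the retained roster and the per-category accounting, which
    conserves individuals: tagged = retained + each exclusion category.
    """
    unknown = set(roster["fate"].unique()) - _KNOWN_FATES
    if unknown:
        raise ValueError(f"unknown fate flag(s): {sorted(unknown)}")
    counts = {
        "tagged": len(roster),
        "excluded_failed": int((roster["fate"] == "failed").sum()),
        "excluded_migrated": int((roster["fate"] == "migrated").sum()),
        "censored_no_departure": 0,
    }
    keep = roster[roster["fate"] == "included"]
    if results is not None:
        scored = keep["individual_id"].map(
            lambda i: results.get(i) is not None and results[i].status == DEPARTED
        )
        counts["censored_no_departure"] = int((~scored).sum())
        keep = keep[scored]
    counts["included"] = len(keep)
    return keep.reset_index(drop=True), counts
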