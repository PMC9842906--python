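"""Synthetic red-kite dispersal studies.

Generates complete studies — broods with covariates, juvenile outcomes,
GPS trajectories, territory centroids, communal roosts and a study polygon
— with the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any field data.

The generative models are linear:

* hatching date (day of year) = intercept + slope * elevation/100 m +
  density and year effects + brood random intercept + within-brood noise;
* departure age (days) = linear predictor over the scaled covariates
  (feeding treatment, scaled hatching date, hatching rank, scaled
  elevation, sex, scaled roost distance, year, scaled territory density,
  year x density and sex x density interactions) + brood random intercept
  + residual.

Trajectories are duty-cycled hourly daylight fixes: a nest-centred bounded
walk with brief excursions before the true departure, an abrupt biased walk
away from the nest afterwards, night-adjacent fixes of departed birds
snapped to the year's communal roosts, plus pre-departure transmitter
failure and pre-departure migration at configurable frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .covariates import GrowthCurve
from .geometry import LocalProjection
from .trackio import TrackSet, tracks_from_frame

__all__ = [
    "HatchModel",
    "DepartureModel",
    "DutyCycle",
    "SimConfig",
    "SyntheticStudy",
    "default_study_polygon",
    "generate_study",
    "generate_tracks",
    "generate_exclusion_roster",
    "truth_report",
    "brood_sizes_for",
]


@dataclass(frozen=True)
class HatchModel:
    """Generative hatching-date model (day of year)."""

    intercept_doy: float = 132.71          # at reference elevation, year 2016
    slope_days_per_100m: float = 3.03      # elevational breeding delay
    density_effect_days: float = -0.69     # per SD of territory density
    year_effect_days: float = -5.99        # 2017 relative to 2016
    brood_sd_days: float = 2.294
    resid_sd_days: float = 1.5             # within-brood hatching spread


@dataclass(frozen=True)
class DepartureModel:
    """Generative departure-age model; slopes act on scaled covariates."""

    intercept: float = 79.47               # control / female / first-hatched / 2016
    feeding: float = -3.52                 # fed vs control
    hatching_date: float = -2.14           # per SD of hatching date
    rank_later: float = 1.49
    rank_singleton: float = 0.24
    elevation: float = 0.39                # per SD of elevation
    sex_male: float = 3.26
    roost_distance: float = -2.90          # per SD of nest-roost distance
    year_2017: float = 4.57
    territory_density: float = -4.99       # per SD of density
    year_density: float = 4.44             # year[2017] x density
    sex_density: float = 3.38              # sex[M] x density
    brood_sd: float = 1.789
    resid_sd: float = 8.0


@dataclass(frozen=True)
class DutyCycle:
    months: tuple[int, ...]
    start_hour_utc: int
    end_hour_utc: int


#: hourly daylight fixes: Feb-Sep 03:00-21:00 UTC, Oct-Jan 05:00-19:00 UTC
DEFAULT_DUTY_CYCLES = (
    DutyCycle(months=(2, 3, 4, 5, 6, 7, 8, 9), start_hour_utc=3, end_hour_utc=21),
    DutyCycle(months=(10, 11, 12, 1), start_hour_utc=5, end_hour_utc=19),
)


def default_study_polygon() -> Polygon:
    """A rectangular ~20 x 23 km study area on the northern pre-Alps."""
    return Polygon(
        [(6.85, 46.66), (7.15, 46.66), (7.15, 46.84), (6.85, 46.84), (6.85, 46.66)]
    )


@dataclass(frozen=True)
class SimConfig:
    n_broods: int = 105
    #: probabilities of 1-4 tagged nestlings per brood (E[size] ~ 1.505,
    #: matching 158 tagged juveniles in 105 broods)
    brood_size_dist: tuple[float, ...] = (0.60, 0.30, 0.095, 0.005)
    elevation_range_m: tuple[float, float] = (524.0, 1129.0)
    hatch_model: HatchModel = HatchModel()
    departure_model: DepartureModel = DepartureModel()
    duty_cycles: tuple[DutyCycle, ...] = DEFAULT_DUTY_CYCLES
    fix_interval_h: float = 1.0
    frac_fed: float = 33.0 / 105.0         # fed broods, stratified per 100 m band
    p_year_2017: float = 0.57
    p_male: float = 85.0 / 158.0
    excursion_rate_per_day: float = 0.1
    excursion_max_h: float = 12.0
    p_return_per_day: float = 0.02         # brief post-departure re-entries
    p_communal_roost: float = 0.333        # share of nights spent at a communal roost
    roost_count_per_year: int = 10
    territories_per_year: int = 130
    p_fail_pre_departure: float = 64.0 / 239.0
    p_migrate_pre_departure: float = 17.0 / 239.0
    tagging_age_d: float = 45.0
    post_departure_track_d: float = 55.0
    fledging_age_d: float = 55.0
    seed: int = 0

    def __post_init__(self):
        if not math.isclose(sum(self.brood_size_dist), 1.0, abs_tol=1e-9):
            raise ValueError("brood_size_dist must sum to 1")
        if any(p < 0 for p in self.brood_size_dist):
            raise ValueError("brood_size_dist probabilities must be >= 0")
        if self.elevation_range_m[0] >= self.elevation_range_m[1]:
            raise ValueError("elevation_range_m must be (low, high) with low < high")
        for sd in (
            self.hatch_model.brood_sd_days,
            self.hatch_model.resid_sd_days,
            self.departure_model.brood_sd,
            self.departure_model.resid_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.fix_interval_h <= 0:
            raise ValueError("fix_interval_h must be > 0")
        if self.p_fail_pre_departure + self.p_migrate_pre_departure > 1:
            raise ValueError("fate probabilities exceed 1")


@dataclass
class SyntheticStudy:
    config: SimConfig
    juveniles: pd.DataFrame          # one row per tagged juvenile
    territory_centroids: pd.DataFrame  # year, lon, lat
    roost_truth: pd.DataFrame        # year, roost, lon, lat
    study_polygon: Polygon
    truth: pd.DataFrame              # per-individual ground truth
    tracks: TrackSet | None = None

    def analysis_table(self) -> pd.DataFrame:
        """Scaled model table over included juveniles (ground-truth outcomes).

        Continuous covariates are centred/scaled within the study; raw
        copies keep a ``_raw`` suffix so mediator models can use natural
        response scales.
        """
        df = self.juveniles[self.juveniles["fate"] == "included"].copy()
        df["departure_age_days"] = self.truth.set_index("individual_id").loc[
            df["individual_id"], "true_departure_age_days"
        ].to_numpy()
        for c in ("hatching_doy", "elevation_m", "roost_distance_m", "territory_density"):
            df[c + "_raw"] = df[c]
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
        return df.reset_index(drop=True)


def brood_sizes_for(n_broods: int, n_juveniles: int) -> np.ndarray:
    """Deterministic brood-size composition hitting an exact juvenile total.

    Uses sizes 1 and 2 only: with 105 broods and 158 juveniles this is
    52 singletons and 53 two-chick broods.
    """
    if not n_broods <= n_juveniles <= 2 * n_broods:
        raise ValueError("need n_broods <= n_juveniles <= 2*n_broods")
    n_two = n_juveniles - n_broods
    return np.array([2] * n_two + [1] * (n_broods - n_two))


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    while len(pts) < n:
        x = rng.uniform(minx, maxx, size=4 * n)
        y = rng.uniform(miny, maxy, size=4 * n)
        for xi, yi in zip(x, y):
            if poly.contains(Point(xi, yi)):
                pts.append((xi, yi))
                if len(pts) == n:
                    break
    return np.array(pts)


def _sample_separated(poly: Polygon, n: int, min_sep_deg: float, rng) -> np.ndarray:
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        (cand,) = _sample_in_polygon(poly, 1, rng)
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep_deg**2 for p in pts):
            pts.append(tuple(cand))
    return np.array(pts)


def _stratified_treatment(elev: np.ndarray, low: float, frac_fed: float, rng) -> np.ndarray:
    """Equal fed proportion within every 100 m elevational band."""
    treat = np.full(len(elev), "control", dtype=object)
    bands = ((elev - low) // 100).astype(int)
    for b in np.unique(bands):
        idx = np.flatnonzero(bands == b)
        n_fed = int(round(frac_fed * len(idx)))
        treat[rng.choice(idx, size=n_fed, replace=False)] = "fed"
    return treat


def generate_study(
    config: SimConfig = SimConfig(),
    fixed_n_juveniles: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticStudy:
    """Draw one synthetic study (no trajectories; see :func:`generate_tracks`).

    ``fixed_n_juveniles`` switches the random brood-size draw to a
    deterministic composition with that exact juvenile total (used by the
    parameter-recovery simulations, which fix n = 158 in 105 broods).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    hm, dm = config.hatch_model, config.departure_model
    low, high = config.elevation_range_m
    poly = default_study_polygon()

    # nests sit >= 2.1 km inside the study boundary so the 2 km density disc
    # is uncorrected (f = 1); edge correction is exercised separately
    proj = LocalProjection(poly.centroid.x, poly.centroid.y)
    ring = np.array(poly.exterior.coords)
    px, py = proj.forward(ring[:, 0], ring[:, 1])
    inner_m = Polygon(np.column_stack([px, py])).buffer(-2100.0)
    ilon, ilat = proj.inverse(*np.array(inner_m.exterior.coords).T)
    inner = Polygon(np.column_stack([ilon, ilat]))

    n_b = config.n_broods
    nests = _sample_in_polygon(inner, n_b, rng)
    elev = rng.uniform(low, high, size=n_b)
    treatment = _stratified_treatment(elev, low, config.frac_fed, rng)
    year = np.where(rng.random(n_b) < config.p_year_2017, 2017, 2016)
    if fixed_n_juveniles is None:
        sizes = rng.choice(
            np.arange(1, len(config.brood_size_dist) + 1), size=n_b, p=config.brood_size_dist
        )
    else:
        sizes = brood_sizes_for(n_b, fixed_n_juveniles)
        rng.shuffle(sizes)

    # territory centroids per year: the year's nests plus background pairs
    cent_rows = []
    for yr in (2016, 2017):
        yr_nests = nests[year == yr]
        extra = _sample_in_polygon(poly, max(config.territories_per_year - len(yr_nests), 0), rng)
        allc = np.vstack([yr_nests, extra]) if len(extra) else yr_nests
        cent_rows.append(pd.DataFrame({"year": yr, "lon": allc[:, 0], "lat": allc[:, 1]}))
    centroids = pd.concat(cent_rows, ignore_index=True)

    # roost truth per year, mutually >= 3 km apart
    roost_rows = []
    for yr in (2016, 2017):
        rp = _sample_separated(poly, config.roost_count_per_year, 3000.0 / 76_000.0, rng)
        roost_rows.append(
            pd.DataFrame({"year": yr, "roost": np.arange(len(rp)), "lon": rp[:, 0], "lat": rp[:, 1]})
        )
    roosts = pd.concat(roost_rows, ignore_index=True)

    # nest-level derived covariates (vectorised; f = 1 by construction)
    dens = np.empty(n_b)
    roost_dist = np.empty(n_b)
    nx, ny = proj.forward(nests[:, 0], nests[:, 1])
    for yr in (2016, 2017):
        sel = year == yr
        cy = centroids[centroids["year"] == yr]
        cx, cyy = proj.forward(cy["lon"].to_numpy(), cy["lat"].to_numpy())
        d2 = (nx[sel, None] - cx[None, :]) ** 2 + (ny[sel, None] - cyy[None, :]) ** 2
        within = (d2 <= 2000.0**2) & (d2 > 100.0**2)  # exclude own territory
        dens[sel] = within.sum(axis=1)
        ry = roosts[roosts["year"] == yr]
        rx, ryy = proj.forward(ry["lon"].to_numpy(), ry["lat"].to_numpy())
        rd2 = (nx[sel, None] - rx[None, :]) ** 2 + (ny[sel, None] - ryy[None, :]) ** 2
        roost_dist[sel] = np.sqrt(rd2.min(axis=1))

    # hatching dates: elevational delay + density/year effects + brood noise
    z_dens_brood = (dens - dens.mean()) / (dens.std(ddof=1) or 1.0)
    hatch_mu = (
        hm.intercept_doy
        + hm.slope_days_per_100m * (elev - (low + high) / 2.0) / 100.0
        + hm.density_effect_days * z_dens_brood
        + hm.year_effect_days * (year == 2017)
    )
    brood_hatch_b = rng.normal(0.0, hm.brood_sd_days, size=n_b)
    brood_dep_b = rng.normal(0.0, dm.brood_sd, size=n_b)

    rows = []
    for b in range(n_b):
        for j in range(sizes[b]):
            rows.append(
                {
                    "individual_id": f"J{b:03d}-{j}",
                    "brood_id": f"B{b:03d}",
                    "nest_lon": nests[b, 0],
                    "nest_lat": nests[b, 1],
                    "elevation_m": elev[b],
                    "treatment": treatment[b],
                    "year": int(year[b]),
                    "sex": "M" if rng.random() < config.p_male else "F",
                    "rank": ("singleton" if sizes[b] == 1 else ("first" if j == 0 else "later")),
                    "n_siblings": int(sizes[b] - 1),
                    "territory_density": dens[b],
                    "roost_distance_m": roost_dist[b],
                    "hatching_doy": hatch_mu[b]
                    + brood_hatch_b[b]
                    + rng.normal(0.0, hm.resid_sd_days),
                    "_brood_dep_b": brood_dep_b[b],
                }
            )
    juv = pd.DataFrame(rows)
    juv["hatching_date"] = pd.to_datetime(juv["year"].astype(str) + "-01-01", utc=True) + pd.to_timedelta(
        juv["hatching_doy"] - 1, unit="D"
    )

    # morphometrics consistent with rank (wing order) and hatch (feather growth)
    n = len(juv)
    juv["tarsus_mm"] = rng.normal(58.0, 2.5, size=n)
    juv["mass_g"] = 120.0 + 14.0 * juv["tarsus_mm"] + rng.normal(0.0, 60.0, size=n)
    meas_age = rng.normal(39.0, 2.0, size=n).clip(30.0, 48.0)
    juv["measurement_date"] = juv["hatching_date"] + pd.to_timedelta(meas_age, unit="D")
    juv["p8_mm"] = GrowthCurve()(meas_age)
    order = juv.groupby("brood_id").cumcount()
    juv["wing_mm"] = 250.0 - 18.0 * order - rng.uniform(0.0, 5.0, size=n)

    # departure ages from the scaled-covariate linear predictor
    z = {
        c: (juv[c] - juv[c].mean()) / juv[c].std(ddof=1)
        for c in ("hatching_doy", "elevation_m", "roost_distance_m", "territory_density")
    }
    fed = (juv["treatment"] == "fed").astype(float)
    male = (juv["sex"] == "M").astype(float)
    y17 = (juv["year"] == 2017).astype(float)
    lp = (
        dm.intercept
        + dm.feeding * fed
        + dm.hatching_date * z["hatching_doy"]
        + dm.rank_later * (juv["rank"] == "later")
        + dm.rank_singleton * (juv["rank"] == "singleton")
        + dm.elevation * z["elevation_m"]
        + dm.sex_male * male
        + dm.roost_distance * z["roost_distance_m"]
        + dm.year_2017 * y17
        + dm.territory_density * z["territory_density"]
        + dm.year_density * y17 * z["territory_density"]
        + dm.sex_density * male * z["territory_density"]
        + juv["_brood_dep_b"]
    )
    eps = rng.normal(0.0, dm.resid_sd, size=n)
    age = lp + eps
    # departure strictly after fledging: redraw the rare residual that is not
    min_age = config.fledging_age_d + 1.0
    for _ in range(100):
        bad = age <= min_age
        if not bad.any():
            break
        age[bad] = lp[bad] + rng.normal(0.0, dm.resid_sd, size=int(bad.sum()))
    age = np.maximum(age, min_age + 0.1)
    juv = juv.drop(columns="_brood_dep_b")

    # fates: mutually exclusive pre-departure failure / migration
    u = rng.random(n)
    fate = np.where(
        u < config.p_fail_pre_departure,
        "failed",
        np.where(u < config.p_fail_pre_departure + config.p_migrate_pre_departure, "migrated", "included"),
    )
    juv["fate"] = fate

    truth = pd.DataFrame(
        {
            "individual_id": juv["individual_id"],
            "brood_id": juv["brood_id"],
            "fate": fate,
            "true_departure_age_days": age,
            "true_departure_t": juv["hatching_date"] + pd.to_timedelta(age, unit="D"),
            "linear_predictor": lp,
        }
    )
    return SyntheticStudy(
        config=config,
        juveniles=juv,
        territory_centroids=centroids,
        roost_truth=roosts,
        study_polygon=poly,
        truth=truth,
    )


def _duty_fix_times(start: pd.Timestamp, end: pd.Timestamp, config: SimConfig) -> pd.DatetimeIndex:
    """All fix timestamps between start and end that fall in a duty window."""
    times = pd.date_range(
        start.ceil(f"{int(config.fix_interval_h * 60)}min"), end, freq=f"{config.fix_interval_h}h", tz="UTC"
    )
    keep = np.zeros(len(times), dtype=bool)
    for cyc in config.duty_cycles:
        keep |= (
            np.isin(times.month, cyc.months)
            & (times.hour >= cyc.start_hour_utc)
            & (times.hour <= cyc.end_hour_utc)
        )
    return times[keep]


def generate_tracks(study: SyntheticStudy, config: SimConfig | None = None, rng=None) -> TrackSet:
    """Simulate duty-cycled GPS trajectories for every tagged juvenile.

    Movement follows the study's ground truth: bounded nest-centred
    positions (plus brief excursions) until the true departure, then a
    biased walk away; departed birds spend day-boundary fixes at the
    year's nearest communal roost.  Failed transmitters truncate before
    departure; migrants leave directly on a one-way >50 km displacement.
    The realised departure fix (first duty-cycle fix at or after the latent
    departure time) is appended to ``study.truth``.
    """
    config = config or study.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    poly = study.study_polygon
    proj = LocalProjection(poly.centroid.x, poly.centroid.y)
    truth = study.truth.set_index("individual_id")

    frames = []
    realized = {}
    for _, ju in study.juveniles.iterrows():
        iid = ju["individual_id"]
        hatch = ju["hatching_date"]
        nest_x, nest_y = proj.forward(ju["nest_lon"], ju["nest_lat"])
        nest_x, nest_y = float(nest_x), float(nest_y)
        dep_t = truth.loc[iid, "true_departure_t"]
        fate = ju["fate"]

        t0 = hatch + pd.Timedelta(days=config.tagging_age_d)
        if fate == "failed":
            t_end = t0 + pd.Timedelta(days=float(rng.uniform(1.0, max((dep_t - t0) / pd.Timedelta(days=1) - 0.5, 1.5))))
            t_end = min(t_end, dep_t - pd.Timedelta(hours=6))
        elif fate == "migrated":
            mig_t = hatch + pd.Timedelta(days=float(rng.uniform(62.0, 85.0)))
            t_end = mig_t + pd.Timedelta(days=10.0)
        else:
            # tracked until autumn migration approaches (end of September)
            season_end = pd.Timestamp(f"{int(ju['year'])}-09-30", tz="UTC")
            t_end = min(dep_t + pd.Timedelta(days=config.post_departure_track_d), season_end)
            t_end = max(t_end, dep_t + pd.Timedelta(days=3.0))
        times = _duty_fix_times(t0, t_end, config)
        if len(times) == 0:
            realized[iid] = np.nan
            continue

        m = len(times)
        dx = rng.normal(0.0, 400.0, size=m)
        dy = rng.normal(0.0, 400.0, size=m)
        rr = np.hypot(dx, dy)
        shrink = np.where(rr > 1800.0, 1800.0 / np.where(rr > 0, rr, 1.0), 1.0)
        x = nest_x + dx * shrink  # home-range residency stays inside the fence
        y = nest_y + dy * shrink
        tdays = (times - hatch) / pd.Timedelta(days=1)

        if fate == "migrated":
            mig_day = (mig_t - hatch) / pd.Timedelta(days=1)
            post = tdays >= mig_day
            theta = rng.uniform(0.0, 2.0 * np.pi)
            r = 100_000.0 * (tdays[post] - mig_day) + 5_000.0
            r = np.minimum(r, 280_000.0)
            x[post] = nest_x + r * np.cos(theta) + rng.normal(0, 500.0, size=int(post.sum()))
            y[post] = nest_y + r * np.sin(theta) + rng.normal(0, 500.0, size=int(post.sum()))
            realized[iid] = np.nan
        else:
            dep_day = (dep_t - hatch) / pd.Timedelta(days=1)
            # brief pre-departure excursions (< 1 day, beyond the 2 km fence)
            n_exc = rng.poisson(config.excursion_rate_per_day * max(dep_day - config.tagging_age_d, 0.0))
            for _ in range(n_exc):
                e0 = rng.uniform(config.tagging_age_d, max(dep_day - 1.0, config.tagging_age_d + 0.1))
                e1 = e0 + rng.uniform(1.0, config.excursion_max_h) / 24.0
                sel = (tdays >= e0) & (tdays < min(e1, dep_day))
                if sel.any():
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    re = rng.uniform(2500.0, 6000.0)
                    x[sel] = nest_x + re * np.cos(theta) + rng.normal(0, 150.0, size=int(sel.sum()))
                    y[sel] = nest_y + re * np.sin(theta) + rng.normal(0, 150.0, size=int(sel.sum()))
            post = tdays >= dep_day
            if post.any():
                theta = rng.uniform(0.0, 2.0 * np.pi)
                drift = rng.uniform(5_000.0, 10_000.0)  # m/day away from the nest
                r = 2_300.0 + drift * (tdays[post] - dep_day)
                r = np.minimum(r, 40_000.0) + rng.normal(0, 300.0, size=int(post.sum()))
                r = np.maximum(r, 2_100.0)  # departed fixes stay beyond the fence
                wob = theta + rng.normal(0, 0.15, size=int(post.sum()))
                x[post] = nest_x + r * np.cos(wob)
                y[post] = nest_y + r * np.sin(wob)
                # rare sub-day returns inside the fence
                days_after = np.unique(np.floor(tdays[post] - dep_day))
                for d in days_after[1:]:
                    if rng.random() < config.p_return_per_day:
                        sel = post & (np.floor(tdays - dep_day) == d)
                        k = np.flatnonzero(sel)
                        if len(k):
                            pick = k[rng.integers(len(k))]
                            x[pick] = nest_x + rng.normal(0, 90.0)
                            y[pick] = nest_y + rng.normal(0, 90.0)
                realized[iid] = float(tdays[post][0])
            else:
                realized[iid] = np.nan

            # departed birds roost communally: each bird rotates through the
            # year's roosts night by night (a random per-bird visiting order),
            # and both night-adjacent fixes — last of the evening, first of
            # the next morning — sit at that night's roost
            if post.any():
                ry = study.roost_truth[study.roost_truth["year"] == ju["year"]]
                rx, ryy = proj.forward(ry["lon"].to_numpy(), ry["lat"].to_numpy())
                dates = times.floor("D")
                first_of_day = pd.Series(times).groupby(dates).transform("min").to_numpy() == times.to_numpy()
                last_of_day = pd.Series(times).groupby(dates).transform("max").to_numpy() == times.to_numpy()
                visit_order = rng.permutation(len(rx))
                # each bird rotates through the year's roosts in its own
                # order; on a configurable share of nights it roosts
                # solitarily within its current range instead
                period = max(int(round(1.0 / config.p_communal_roost)), 1)
                night_roost = {
                    d: int(visit_order[(i // period) % len(rx)]) if i % period == 0 else -1
                    for i, d in enumerate(pd.unique(dates))
                }
                for k in np.flatnonzero(post & last_of_day):
                    j = night_roost[dates[k]]
                    if j >= 0:
                        x[k] = rx[j] + rng.normal(0, 90.0)
                        y[k] = ryy[j] + rng.normal(0, 90.0)
                day = pd.Timedelta(days=1)
                for k in np.flatnonzero(post & first_of_day):
                    j = night_roost.get(dates[k] - day, -1)
                    if j >= 0:
                        x[k] = rx[j] + rng.normal(0, 90.0)
                        y[k] = ryy[j] + rng.normal(0, 90.0)

        lon, lat = proj.inverse(x, y)
        frames.append(
            pd.DataFrame({"individual_id": iid, "t": times, "lon": lon, "lat": lat})
        )

    fixes = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["individual_id", "t", "lon", "lat"]
    )
    trackset = tracks_from_frame(fixes)
    study.truth = study.truth.merge(
        pd.Series(realized, name="true_departure_fix_age_days").rename_axis("individual_id").reset_index(),
        on="individual_id",
        how="left",
    )
    study.tracks = trackset
    return trackset


def generate_exclusion_roster(
    n_tagged: int, n_failed: int, n_migrated: int, rng=None
) -> pd.DataFrame:
    """A tagging roster with mutually exclusive fate flags at exact counts."""
    if min(n_tagged, n_failed, n_migrated) < 0:
        raise ValueError("counts must be non-negative")
    if n_failed + n_migrated > n_tagged:
        raise ValueError("n_failed + n_migrated exceeds n_tagged")
    fate = np.array(
        ["failed"] * n_failed
        + ["migrated"] * n_migrated
        + ["included"] * (n_tagged - n_failed - n_migrated),
        dtype=object,
    )
    if rng is not None:
        rng.shuffle(fate)
    return pd.DataFrame(
        {"individual_id": [f"T{i:04d}" for i in range(n_tagged)], "fate": fate}
    )


def truth_report(study: SyntheticStudy) -> pd.DataFrame:
    """Per-individual ground truth for test assertions (one row per juvenile)."""
    return study.truth.copy().reset_index(drop=True)
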