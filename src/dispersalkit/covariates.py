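"""Per-juvenile model covariates.

Derives the predictors of the departure-age analysis: edge-corrected
conspecific territory density, hatching date inverted from the eighth
primary's length via a growth curve, within-brood hatching rank from wing
lengths, body-condition residuals from a mass–size regression, and the
assembled analysis table with every continuous variable centred and scaled
(the scaling metadata is retained so coefficients can be reported back in
natural units such as days per 100 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

from .geometry import LocalProjection, geodesic_distance_m

CONTINUOUS_COLUMNS = ["hatching_doy", "elevation_m", "roost_distance_m", "territory_density"]

__all__ = [
    "territory_density",
    "GrowthCurve",
    "hatch_date_from_feather",
    "hatching_rank",
    "body_condition",
    "ScalingMeta",
    "assemble_table",
    "correlation_screen",
]


def territory_density(
    nest: tuple[float, float],
    centroids: pd.DataFrame,
    study_polygon: Polygon,
    radius_m: float = 2000.0,
    exclude_own: bool = True,
    own_radius_m: float = 100.0,
) -> float:
    """Edge-corrected count of territory centroids within ``radius_m`` of a nest.

    The raw count excludes the focal pair's own territory (any centroid
    within ``own_radius_m`` of the nest) and is inflated by 1/f where f is
    the fraction of the disc's area lying inside the study polygon, so
    densities at the study-area edge are proportionally corrected.

    Raises
    ------
    ValueError
        If the disc lies wholly outside the polygon (f = 0).
    """
    lon, lat = nest
    d = geodesic_distance_m(centroids["lon"].to_numpy(), centroids["lat"].to_numpy(), lon, lat)
    inside = d <= radius_m
    if exclude_own:
        inside &= d > own_radius_m
    raw = int(np.sum(inside))

    proj = LocalProjection(lon, lat)
    px, py = proj.forward(
        np.array(study_polygon.exterior.coords)[:, 0],
        np.array(study_polygon.exterior.coords)[:, 1],
    )
    poly_m = Polygon(np.column_stack([px, py]))
    disc = Point(0.0, 0.0).buffer(radius_m, quad_segs=256)
    f = disc.intersection(poly_m).area / disc.area
    if f <= 0:
        raise ValueError("nest disc lies entirely outside the study polygon (f=0)")
    return raw / f


@dataclass(frozen=True)
class GrowthCurve:
    """Parametric age -> eighth-primary-length curve (logistic by default).

    L(a) = asymptote / (1 + exp(-rate * (a - midpoint))), strictly increasing
    on [age_min, age_max].  Parameters are configuration, not literature
    values: real deployments supply a population-specific curve.
    """

    asymptote_mm: float = 380.0
    midpoint_d: float = 32.0
    rate_per_d: float = 0.12
    age_min_d: float = 5.0
    age_max_d: float = 80.0

    def __call__(self, age_d):
        return self.asymptote_mm / (1.0 + np.exp(-self.rate_per_d * (np.asarray(age_d, float) - self.midpoint_d)))

    @property
    def support_mm(self) -> tuple[float, float]:
        return float(self(self.age_min_d)), float(self(self.age_max_d))


def hatch_date_from_feather(
    p8_mm: float, measurement_date, growth_curve: GrowthCurve = GrowthCurve()
) -> pd.Timestamp:
    """Hatching date from feather length: invert the growth curve, subtract the age.

    The inversion is a bracketed monotone root find (well below 0.01 d error).
    """
    lo, hi = growth_curve.support_mm
    if not (lo <= p8_mm <= hi):
        raise ValueError(
            f"p8 length {p8_mm} mm outside growth-curve range [{lo:.1f}, {hi:.1f}] mm"
        )
    age = brentq(
        lambda a: growth_curve(a) - p8_mm,
        growth_curve.age_min_d,
        growth_curve.age_max_d,
        xtol=1e-6,
    )
    return pd.Timestamp(measurement_date) - pd.Timedelta(days=float(age))


def hatching_rank(siblings: pd.DataFrame) -> pd.Series:
    """Rank classes within one brood from wing lengths.

    Longest wing is first-hatched; the rest are "later"; an only nestling is
    "singleton".  Wing ties break by body mass (heavier earlier), then by
    individual id.
    """
    if len(siblings) == 0:
        return pd.Series(dtype=object)
    if len(siblings) == 1:
        return pd.Series(["singleton"], index=siblings.index)
    order = siblings.sort_values(
        by=["wing_mm", "mass_g", "individual_id"], ascending=[False, False, True]
    ).index
    ranks = pd.Series("later", index=siblings.index, dtype=object)
    ranks[order[0]] = "first"
    return ranks


def body_condition(records: pd.DataFrame) -> pd.Series:
    """Mass–size body-condition residuals over a population table.

    OLS of ``mass_g`` on ``tarsus_mm``; the residual of each bird is its
    condition index (residuals sum to zero by construction).
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records to fit the mass-size relationship")
    if np.isclose(records["tarsus_mm"].std(ddof=0), 0.0):
        raise ValueError("zero variance in tarsus length: mass-size fit undefined")
    X = sm.add_constant(records["tarsus_mm"].to_numpy())
    fit = sm.OLS(records["mass_g"].to_numpy(), X).fit()
    return pd.Series(fit.resid, index=records.index, name="body_condition")


@dataclass
class ScalingMeta:
    """Centre/scale parameters per continuous column, for back-transformation."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def scale(self, table: pd.DataFrame, columns) -> pd.DataFrame:
        out = table.copy()
        for c in columns:
            mu, sd = float(table[c].mean()), float(table[c].std(ddof=1))
            if sd == 0:
                raise ValueError(f"cannot scale constant column {c!r}")
            self.mean[c], self.sd[c] = mu, sd
            out[c] = (table[c] - mu) / sd
        return out

    def unscale_slope(self, column: str, scaled_slope: float, per_natural_units: float = 1.0) -> float:
        """Scaled-x slope -> natural-unit slope (e.g. per_natural_units=100 for d/100 m)."""
        return scaled_slope / self.sd[column] * per_natural_units


def assemble_table(
    records: pd.DataFrame,
    departures: pd.DataFrame,
    densities: pd.Series | None = None,
    roost_distances: pd.Series | None = None,
) -> tuple[pd.DataFrame, ScalingMeta, pd.DataFrame]:
    """Join records + departure ages (+ optional derived covariates), filter, scale.

    ``records`` carries one row per juvenile with the metadata covariates;
    ``departures`` has ``individual_id``, ``status`` and
    ``departure_age_days``.  Only individuals with a scored departure enter
    the table.  Unmatched keys are returned in the reject frame, never
    silently dropped.

    Returns (scaled table, scaling metadata, rejects).
    """
    rec = records.copy()
    if densities is not None:
        rec["territory_density"] = rec["individual_id"].map(densities)
    if roost_distances is not None:
        rec["roost_distance_m"] = rec["individual_id"].map(roost_distances)

    dep = departures[departures["status"] == "departed"][["individual_id", "departure_age_days"]]
    merged = rec.merge(dep, on="individual_id", how="outer", indicator=True)
    rejects = merged[merged["_merge"] != "both"].copy()
    rejects["reason"] = np.where(
        rejects["_merge"] == "left_only", "no scored departure", "departure without metadata"
    )
    table = merged[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)

    model_cols = ["departure_age_days", "treatment", "sex", "rank", "year", "brood_id"] + [
        c for c in CONTINUOUS_COLUMNS if c in table.columns
    ]
    missing = table[model_cols].isna().any(axis=1)
    if missing.any():
        miss = table[missing].assign(reason="missing model covariate", _merge="both")
        rejects = pd.concat([rejects, miss], ignore_index=True)
        table = table[~missing].reset_index(drop=True)

    meta = ScalingMeta()
    cont = [c for c in CONTINUOUS_COLUMNS if c in table.columns]
    for c in cont:  # mediator models regress on the natural response scale
        table[c + "_raw"] = table[c]
    scaled = meta.scale(table, cont)
    return scaled, meta, rejects.drop(columns="_merge", errors="ignore").reset_index(drop=True)


def correlation_screen(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Report continuous-predictor pairs with |Pearson r| above the threshold."""
    cols = [c for c in CONTINUOUS_COLUMNS if c in table.columns]
    corr = table[cols].corr()
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) > threshold:
                rows.append({"var_a": a, "var_b": b, "r": float(r)})
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "r"])
    if len(out):
        warnings.warn(f"{len(out)} predictor pair(s) with |r| > {threshold}")
    return out
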