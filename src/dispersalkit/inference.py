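"""Model suite for the departure-age analysis.

The inferential chain mirrors a three-step design: (1) a linear mixed model
of departure age on feeding treatment, hatching date, rank, elevation, sex,
roost distance, year and territory density, with brood as a random
intercept (REML), all two-way candidate interactions pruned stepwise;
(2) mixed/linear models of the mediators (hatching date, territory density,
roost distance) on elevation; (3) a path analysis decomposing the elevation
effect on departure age into its direct path and its indirect path through
hatching date.

Uncertainty is summarised by 95% credible intervals from a simulated
posterior: 2000 multivariate-normal draws centred at the estimates with the
fitted fixed-effect covariance (the random-effect variance held at its REML
estimate).  The brood random effect is tested by a likelihood-ratio test
against the model without random structure, with a parametric-bootstrap
null because the variance sits on the boundary of its parameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PathResult",
    "fit_model",
    "prune_interactions",
    "simulate_cri",
    "random_effect_lrt",
    "path_analysis",
    "predict_effects",
    "DEPARTURE_SPEC",
    "HATCH_SPEC",
    "DENSITY_SPEC",
    "ROOST_DISTANCE_SPEC",
]


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[str, ...]
    interactions: tuple[str, ...] = ()
    group: str | None = None  # random-intercept grouping column, e.g. brood_id
    reml: bool = True

    def formula(self, interactions: tuple[str, ...] | None = None) -> str:
        terms = list(self.fixed) + list(self.interactions if interactions is None else interactions)
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def __post_init__(self):
        for ix in self.interactions:
            for part in ix.split(":"):
                if part not in self.fixed:
                    raise ValueError(f"interaction {ix!r} references undeclared main effect {part!r}")


#: the departure-age mixed model (final retained interactions)
DEPARTURE_SPEC = ModelSpec(
    response="departure_age_days",
    fixed=(
        "treatment",
        "hatching_doy",
        "rank",
        "elevation_m",
        "sex",
        "roost_distance_m",
        "C(year)",
        "territory_density",
    ),
    interactions=("C(year):territory_density", "sex:territory_density"),
    group="brood_id",
)

#: hatching-date mixed model (mediator model of the path analysis)
HATCH_SPEC = ModelSpec(
    response="hatching_doy_raw",
    fixed=("elevation_m", "territory_density", "C(year)"),
    group="brood_id",
)

DENSITY_SPEC = ModelSpec(
    response="territory_density_raw", fixed=("elevation_m", "C(year)"), group=None
)

ROOST_DISTANCE_SPEC = ModelSpec(
    response="roost_distance_m_raw",
    fixed=("elevation_m", "territory_density", "C(year)"),
    group=None,
)


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series          # fixed-effect estimates
    se: pd.Series
    cov: pd.DataFrame          # fixed-effect covariance
    re_sd: float | None        # random-intercept SD (None for OLS)
    resid_sd: float
    llf: float
    n_obs: int
    n_groups: int | None
    result: object = field(repr=False, default=None)
    cri: pd.DataFrame | None = None
    pruning_trace: list[dict] = field(default_factory=list)

    @property
    def coef_table(self) -> pd.DataFrame:
        tbl = pd.DataFrame({"estimate": self.params, "se": self.se})
        if self.cri is not None:
            tbl = tbl.join(self.cri)
        return tbl

    def wald_p(self) -> pd.Series:
        """Two-sided normal-reference p-values for the fixed effects."""
        z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)


def fit_model(spec: ModelSpec, table: pd.DataFrame, formula: str | None = None) -> ModelFit:
    """Fit a mixed model (REML) when the spec declares a grouping, else OLS."""
    formula = formula or spec.formula()
    if table[sorted(_referenced(formula, table))].isna().any().any():
        raise ValueError("model columns contain missing values")

    if spec.group is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, table, groups=table[spec.group])
            res = model.fit(reml=spec.reml)
        k = len(res.fe_params)
        names = list(res.fe_params.index)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k, :k], index=names, columns=names
        )
        re_var = float(np.asarray(res.cov_re)[0, 0])
        fit = ModelFit(
            spec=spec,
            params=res.fe_params.copy(),
            se=res.bse_fe.copy(),
            cov=cov,
            re_sd=float(np.sqrt(max(re_var, 0.0))),
            resid_sd=float(np.sqrt(res.scale)),
            llf=float(res.llf),
            n_obs=int(res.nobs),
            n_groups=int(table[spec.group].nunique()),
            result=res,
        )
    else:
        res = smf.ols(formula, table).fit()
        fit = ModelFit(
            spec=spec,
            params=res.params.copy(),
            se=res.bse.copy(),
            cov=pd.DataFrame(res.cov_params()),
            re_sd=None,
            resid_sd=float(np.sqrt(res.mse_resid)),
            llf=float(res.llf),
            n_obs=int(res.nobs),
            n_groups=None,
            result=res,
        )
    return fit


def _referenced(formula: str, table: pd.DataFrame) -> set[str]:
    return {c for c in table.columns if c in formula}


def prune_interactions(spec: ModelSpec, table: pd.DataFrame, alpha: float = 0.05) -> ModelFit:
    """Stepwise removal of non-significant candidate interactions.

    Refits after dropping the least-significant interaction (largest Wald p
    >= alpha, normal reference) until every remaining interaction is
    significant.  Main effects are never dropped, matching the convention
    of retaining non-significant fixed effects.  The trace of every step is
    kept on the returned fit.
    """
    remaining = list(spec.interactions)
    trace: list[dict] = []
    while True:
        fit = fit_model(spec, table, formula=spec.formula(tuple(remaining)))
        if not remaining:
            break
        pvals = fit.wald_p()
        # map declared interaction terms to design-matrix coefficient names
        cand_p = {}
        for ix in remaining:
            parts = ix.split(":")
            hits = [
                n
                for n in pvals.index
                if ":" in n and all(any(p in piece for piece in n.split(":")) for p in parts)
            ]
            cand_p[ix] = float(pvals[hits].min()) if hits else 1.0
        worst = max(cand_p, key=cand_p.get)
        if cand_p[worst] < alpha:
            break
        trace.append({"dropped": worst, "p": cand_p[worst], "remaining": list(remaining)})
        remaining.remove(worst)
    fit.pruning_trace = trace
    return fit


def _check_pd(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, float)
    cov = (cov + cov.T) / 2
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(abs(w.max()), 1.0):
        raise ValueError(
            "coefficient covariance is not positive semi-definite; "
            "consider projecting to the nearest PD matrix (clip negative eigenvalues)"
        )
    return cov


def simulate_cri(
    fit: ModelFit, n_draws: int = 2000, level: float = 0.95, seed: int = 0
) -> pd.DataFrame:
    """Simulated-posterior credible intervals for the fixed effects.

    Draws ``n_draws`` coefficient vectors from N(estimates, covariance) and
    takes the (1-level)/2 tail percentiles.  Deterministic under the seed.
    The intervals are attached to the fit and returned.
    """
    cov = _check_pd(fit.cov.to_numpy())
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.params.to_numpy(), cov, size=n_draws, method="eigh")
    lo, hi = np.percentile(draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2], axis=0)
    cri = pd.DataFrame({"cri_lo": lo, "cri_hi": hi}, index=fit.params.index)
    fit.cri = cri
    return cri


def coefficient_draws(fit: ModelFit, n_draws: int, seed: int) -> pd.DataFrame:
    """Posterior-simulation coefficient draws (rows) used by downstream summaries."""
    cov = _check_pd(fit.cov.to_numpy())
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.params.to_numpy(), cov, size=n_draws, method="eigh")
    return pd.DataFrame(draws, columns=fit.params.index)


def random_effect_lrt(
    spec: ModelSpec, table: pd.DataFrame, n_null_sims: int = 500, seed: int = 0
) -> dict:
    """Likelihood-ratio test of the random intercept with a simulated null.

    The observed statistic is 2*(ML log-likelihood of the mixed model minus
    that of the OLS model).  Because the null puts the variance on the
    boundary, the reference distribution is built by parametric bootstrap:
    simulate responses from the fitted OLS model, refit both models, and
    take the bootstrap tail probability.
    """
    if n_null_sims < 100:
        warnings.warn("n_null_sims < 100 gives a coarse bootstrap p-value")
    if spec.group is None:
        raise ValueError("spec has no random-effect grouping to test")

    formula = spec.formula()
    ols_spec = ModelSpec(spec.response, spec.fixed, spec.interactions, group=None)

    def _stat(df: pd.DataFrame) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll_mix = smf.mixedlm(formula, df, groups=df[spec.group]).fit(reml=False).llf
        ll_ols = smf.ols(formula, df).fit().llf
        return max(0.0, 2.0 * float(ll_mix - ll_ols))

    observed = _stat(table)
    ols = smf.ols(formula, table).fit()
    mu = np.asarray(ols.fittedvalues)
    sigma = float(np.sqrt(ols.scale))
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_null_sims)
    sim = table.copy()
    for i in range(n_null_sims):
        sim[spec.response] = mu + rng.normal(0.0, sigma, size=len(mu))
        null_stats[i] = _stat(sim)
    p = (1.0 + np.sum(null_stats >= observed)) / (1.0 + n_null_sims)
    return {"statistic": observed, "p": float(p), "null_stats": null_stats}


@dataclass
class PathResult:
    """Direct and indirect (via hatching date) elevation effects on departure age."""

    a: float                     # elevation -> hatching date (scaled elevation)
    b: float                     # hatching date -> departure age (scaled hatch)
    indirect: float              # a*b on the departure-age scale
    direct: float                # elevation coefficient of the departure model
    intervals: pd.DataFrame      # rows a, b, indirect, direct, total
    natural: dict = field(default_factory=dict)  # d/100 m chain when scaling known


def path_analysis(
    fit_hatch: ModelFit,
    fit_departure: ModelFit,
    n_draws: int = 2000,
    seed: int = 0,
    scaling=None,
    elevation_term: str = "elevation_m",
    hatch_term: str = "hatching_doy",
) -> PathResult:
    """Product-of-coefficients path analysis with joint posterior simulation.

    Per joint draw, the indirect effect is the product of the
    elevation->hatching slope (mediator model) and the hatching->departure
    slope; the direct effect is the departure model's elevation
    coefficient.  Intervals are draw percentiles.  When scaling metadata is
    supplied, the chain is also reported in natural units: days of hatching
    per 100 m elevation, and days of departure age per 100 m.
    """
    if elevation_term not in fit_hatch.params or elevation_term not in fit_departure.params:
        raise ValueError(f"both fits must contain the {elevation_term!r} term")
    da = coefficient_draws(fit_hatch, n_draws, seed)[elevation_term]
    dep_draws = coefficient_draws(fit_departure, n_draws, seed + 1)
    db = dep_draws[hatch_term]
    ddir = dep_draws[elevation_term]
    dind = da.to_numpy() * db.to_numpy()
    dtot = dind + ddir.to_numpy()

    def _ci(x):
        lo, hi = np.percentile(x, [2.5, 97.5])
        return {"estimate": float(np.mean(x)), "cri_lo": float(lo), "cri_hi": float(hi)}

    intervals = pd.DataFrame(
        {
            "a": _ci(da),
            "b": _ci(db),
            "indirect": _ci(dind),
            "direct": _ci(ddir),
            "total": _ci(dtot),
        }
    ).T

    a = float(fit_hatch.params[elevation_term])
    b = float(fit_departure.params[hatch_term])
    direct = float(fit_departure.params[elevation_term])
    natural = {}
    if scaling is not None:
        sd_elev = scaling.sd["elevation_m"]
        sd_hatch = scaling.sd["hatching_doy"]
        a_nat = a / sd_elev * 100.0            # days of hatching per 100 m
        b_nat = b / sd_hatch                   # departure days per hatching day
        natural = {
            "hatch_days_per_100m": a_nat,
            "departure_days_per_hatch_day": b_nat,
            "indirect_days_per_100m": a_nat * b_nat,
            "direct_days_per_100m": direct / sd_elev * 100.0,
        }
    return PathResult(a=a, b=b, indirect=a * b, direct=direct, intervals=intervals, natural=natural)


def predict_effects(
    fit: ModelFit, scenarios: pd.DataFrame, n_draws: int = 2000, level: float = 0.95, seed: int = 0
) -> pd.DataFrame:
    """Point predictions with draw-based credible bands over a scenario grid.

    Scenario columns must use the model's variable names and factor levels;
    an unknown factor level raises.  Continuous covariates are interpreted
    on the same (scaled) scale the model was fitted on.
    """
    res = fit.result
    design_info = res.model.data.design_info
    from patsy import build_design_matrices

    try:
        (X,) = build_design_matrices([design_info], scenarios)
    except Exception as exc:  # unknown level or missing column
        raise ValueError(f"invalid scenario grid: {exc}") from exc
    X = np.asarray(X)
    draws = coefficient_draws(fit, n_draws, seed).to_numpy()
    pred = X @ fit.params.to_numpy()
    band = X @ draws.T
    lo, hi = np.percentile(band, [100 * (1 - level) / 2, 100 * (1 + level) / 2], axis=1)
    out = scenarios.copy()
    out["predicted"] = pred
    out["cri_lo"] = lo
    out["cri_hi"] = hi
    return out
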