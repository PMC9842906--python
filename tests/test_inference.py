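"""Model suite: REML mixed fits, interaction pruning, simulated-posterior
intervals, the random-effect bootstrap LRT, and the path analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dispersalkit import simulate as sim
from dispersalkit.inference import (
    DEPARTURE_SPEC,
    HATCH_SPEC,
    ModelSpec,
    coefficient_draws,
    fit_model,
    path_analysis,
    predict_effects,
    prune_interactions,
    random_effect_lrt,
    simulate_cri,
)


def noise_free_table(seed=0, n_juv=120):
    """Departure ages equal to their linear predictor exactly.

    Hatching dates keep their own noise so the covariates stay linearly
    independent (noise-free mediation would make the design singular).
    """
    cfg = dataclasses.replace(
        sim.SimConfig(seed=seed, n_broods=80),
        departure_model=dataclasses.replace(sim.DepartureModel(), brood_sd=0.0, resid_sd=0.0),
        p_fail_pre_departure=0.0,
        p_migrate_pre_departure=0.0,
    )
    study = sim.generate_study(cfg, fixed_n_juveniles=n_juv)
    return study, study.analysis_table()


def noisy_table(seed=0):
    cfg = dataclasses.replace(
        sim.SimConfig(seed=seed), p_fail_pre_departure=0.0, p_migrate_pre_departure=0.0
    )
    study = sim.generate_study(cfg, fixed_n_juveniles=158)
    return study.analysis_table()


class TestFitModel:
    def test_noise_free_exact_recovery(self):
        _, tab = noise_free_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        dm = sim.DepartureModel()
        expect = {
            "treatment[T.fed]": dm.feeding,
            "hatching_doy": dm.hatching_date,
            "sex[T.M]": dm.sex_male,
            "roost_distance_m": dm.roost_distance,
            "C(year)[T.2017]": dm.year_2017,
            "territory_density": dm.territory_density,
            "C(year)[T.2017]:territory_density": dm.year_density,
            "sex[T.M]:territory_density": dm.sex_density,
            "rank[T.later]": dm.rank_later,
            "rank[T.singleton]": dm.rank_singleton,
            "elevation_m": dm.elevation,
            "Intercept": dm.intercept,
        }
        for term, truth in expect.items():
            assert fit.params[term] == pytest.approx(truth, abs=1e-6), term

    def test_zero_variance_response(self):
        _, tab = noise_free_table()
        tab = tab.copy()
        tab["departure_age_days"] = 84.0
        spec = ModelSpec("departure_age_days", ("elevation_m", "territory_density"))
        fit = fit_model(spec, tab)
        assert fit.params["Intercept"] == pytest.approx(84.0)
        assert fit.params["elevation_m"] == pytest.approx(0.0, abs=1e-10)

    def test_mixed_fit_reports_structure(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        assert fit.n_obs == 158
        assert fit.n_groups == 105
        assert fit.re_sd is not None and fit.re_sd >= 0
        assert fit.cov.shape == (len(fit.params), len(fit.params))

    def test_missing_values_rejected(self):
        tab = noisy_table()
        tab.loc[0, "elevation_m"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_model(DEPARTURE_SPEC, tab)


class TestSimulateCri:
    def test_single_coefficient_normal_quantiles(self):
        tab = noisy_table()
        fit = fit_model(ModelSpec("departure_age_days", ("elevation_m",)), tab)
        cri = simulate_cri(fit, n_draws=20000, seed=0)
        est, se = fit.params["elevation_m"], fit.se["elevation_m"]
        assert cri.loc["elevation_m", "cri_lo"] == pytest.approx(est - 1.96 * se, abs=0.08 * se)
        assert cri.loc["elevation_m", "cri_hi"] == pytest.approx(est + 1.96 * se, abs=0.08 * se)

    def test_zero_covariance_degenerate_interval(self):
        tab = noisy_table()
        fit = fit_model(ModelSpec("departure_age_days", ("elevation_m",)), tab)
        fit.cov.iloc[:, :] = 0.0
        cri = simulate_cri(fit, n_draws=200, seed=0)
        assert (cri["cri_lo"] == cri["cri_hi"]).all()

    def test_same_seed_identical(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        a = simulate_cri(fit, seed=11)
        b = simulate_cri(fit, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_covariance_rejected(self):
        tab = noisy_table()
        fit = fit_model(ModelSpec("departure_age_days", ("elevation_m",)), tab)
        fit.cov.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_cri(fit)


class TestPruneInteractions:
    def test_zero_candidates_identity(self):
        tab = noisy_table()
        spec = ModelSpec("departure_age_days", ("elevation_m", "treatment"))
        fit = prune_interactions(spec, tab)
        assert fit.pruning_trace == []
        assert set(fit.params.index) == {"Intercept", "elevation_m", "treatment[T.fed]"}

    def test_strong_interaction_retained_weak_dropped(self):
        # the generator plants sex x density and year x density; elevation
        # interactions are absent from the truth and should mostly go
        retained = 0
        for seed in range(8):
            tab = noisy_table(seed)
            spec = ModelSpec(
                DEPARTURE_SPEC.response,
                DEPARTURE_SPEC.fixed,
                (
                    "treatment:elevation_m",
                    "C(year):territory_density",
                    "sex:territory_density",
                ),
                group="brood_id",
            )
            fit = prune_interactions(spec, tab)
            terms = set(fit.params.index)
            retained += "sex[T.M]:territory_density" in terms
            # main effects survive every pruning path
            assert "treatment[T.fed]" in terms
            assert "elevation_m" in terms
        assert retained >= 6  # planted effect (3.38 d / SD) found in most replicates

    def test_trace_records_dropped_terms(self):
        tab = noisy_table()
        spec = ModelSpec(
            DEPARTURE_SPEC.response,
            DEPARTURE_SPEC.fixed,
            ("treatment:elevation_m", "rank:elevation_m"),
            group="brood_id",
        )
        fit = prune_interactions(spec, tab)
        dropped = {step["dropped"] for step in fit.pruning_trace}
        for term in dropped:
            assert term in ("treatment:elevation_m", "rank:elevation_m")


class TestRandomEffectLrt:
    def test_statistic_non_negative_and_null_case(self):
        _, tab = noise_free_table()
        tab = tab.copy()
        rng = np.random.default_rng(0)
        # no brood structure in the residuals
        tab["departure_age_days"] = tab["departure_age_days"] + rng.normal(0, 8, len(tab))
        spec = ModelSpec("departure_age_days", ("elevation_m", "treatment"), group="brood_id")
        out = random_effect_lrt(spec, tab, n_null_sims=100, seed=0)
        assert out["statistic"] >= 0.0
        # a single replicate's p-value is uniform under the null, so only
        # require that the test does not call the null strongly significant
        assert out["p"] >= 0.01

    def test_planted_brood_variance_detected(self):
        cfg = dataclasses.replace(
            sim.SimConfig(seed=4),
            departure_model=dataclasses.replace(sim.DepartureModel(), brood_sd=8.0, resid_sd=3.0),
            p_fail_pre_departure=0.0,
            p_migrate_pre_departure=0.0,
        )
        tab = sim.generate_study(cfg, fixed_n_juveniles=158).analysis_table()
        spec = ModelSpec("departure_age_days", ("elevation_m", "treatment"), group="brood_id")
        out = random_effect_lrt(spec, tab, n_null_sims=100, seed=0)
        assert out["p"] < 0.02

    def test_too_few_sims_warns(self):
        tab = noisy_table()
        spec = ModelSpec("departure_age_days", ("elevation_m",), group="brood_id")
        with pytest.warns(UserWarning, match="coarse"):
            random_effect_lrt(spec, tab, n_null_sims=20, seed=0)


class TestPathAnalysis:
    def fits(self, table):
        return fit_model(HATCH_SPEC, table), fit_model(DEPARTURE_SPEC, table)

    def test_indirect_is_product_of_paths(self):
        tab = noisy_table()
        fh, fd = self.fits(tab)
        res = path_analysis(fh, fd, n_draws=500, seed=0)
        assert res.indirect == pytest.approx(res.a * res.b)

    def test_zero_mediation_interval_covers_zero(self):
        cfg = dataclasses.replace(
            sim.SimConfig(seed=9),
            departure_model=dataclasses.replace(sim.DepartureModel(), hatching_date=0.0),
            p_fail_pre_departure=0.0,
            p_migrate_pre_departure=0.0,
        )
        tab = sim.generate_study(cfg, fixed_n_juveniles=158).analysis_table()
        fh, fd = self.fits(tab)
        res = path_analysis(fh, fd, n_draws=2000, seed=0)
        lo, hi = res.intervals.loc["indirect", ["cri_lo", "cri_hi"]]
        assert lo <= 0.0 <= hi

    def test_noise_free_decomposition_matches_total_regression(self):
        # constructed linear system: x -> m -> y plus a direct x -> y path,
        # y exactly linear; then direct + b*a_hat equals the reduced-form
        # slope of y on x by OLS algebra
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        m = 1.7 * x + rng.normal(0, 0.6, 200)  # mediator keeps its own noise
        y = 0.8 * x + 2.5 * m                  # outcome is exact
        tab = pd.DataFrame({"elevation_m": x, "hatching_doy": m, "departure_age_days": y})
        fh = fit_model(ModelSpec("hatching_doy", ("elevation_m",)), tab)
        fd = fit_model(ModelSpec("departure_age_days", ("elevation_m", "hatching_doy")), tab)
        res = path_analysis(fh, fd, n_draws=100, seed=0)
        total = fit_model(ModelSpec("departure_age_days", ("elevation_m",)), tab).params[
            "elevation_m"
        ]
        assert res.direct == pytest.approx(0.8, abs=1e-9)
        assert res.b == pytest.approx(2.5, abs=1e-9)
        assert res.direct + res.indirect == pytest.approx(total, abs=1e-9)

    def test_natural_units_chain(self):
        tab = noisy_table()
        fh, fd = self.fits(tab)

        class Meta:  # minimal scaling metadata
            sd = {
                "elevation_m": tab["elevation_m_raw"].std(ddof=1),
                "hatching_doy": tab["hatching_doy_raw"].std(ddof=1),
            }

        res = path_analysis(fh, fd, n_draws=200, seed=0, scaling=Meta())
        assert res.natural["hatch_days_per_100m"] == pytest.approx(3.03, abs=1.0)
        assert res.natural["indirect_days_per_100m"] == pytest.approx(
            res.natural["hatch_days_per_100m"] * res.natural["departure_days_per_hatch_day"]
        )


class TestPredictEffects:
    def scenario(self, **overrides):
        base = {
            "treatment": "control",
            "hatching_doy": 0.0,
            "rank": "later",
            "elevation_m": 0.0,
            "sex": "M",
            "roost_distance_m": 0.0,
            "C(year)": None,  # unused; year passed directly
            "year": 2017,
            "territory_density": 0.0,
        }
        base.update(overrides)
        base.pop("C(year)")
        return base

    def test_feeding_contrast_equals_coefficient(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        grid = pd.DataFrame([self.scenario(), self.scenario(treatment="fed")])
        pred = predict_effects(fit, grid, n_draws=200, seed=0)
        diff = pred["predicted"].iloc[1] - pred["predicted"].iloc[0]
        assert diff == pytest.approx(fit.params["treatment[T.fed]"], abs=1e-9)

    def test_reference_scenario_is_intercept(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        grid = pd.DataFrame(
            [self.scenario(treatment="control", sex="F", rank="first", year=2016)]
        )
        pred = predict_effects(fit, grid, n_draws=200, seed=0)
        assert pred["predicted"].iloc[0] == pytest.approx(fit.params["Intercept"], abs=1e-9)

    def test_monotone_decline_in_hatching_date(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        grid = pd.DataFrame([self.scenario(hatching_doy=z) for z in (-2.0, -1.0, 0.0, 1.0, 2.0)])
        pred = predict_effects(fit, grid, n_draws=100, seed=0)
        if fit.params["hatching_doy"] < 0:
            assert pred["predicted"].is_monotonic_decreasing

    def test_unknown_level_rejected(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        grid = pd.DataFrame([self.scenario(sex="X")])
        with pytest.raises(ValueError, match="scenario"):
            predict_effects(fit, grid)

    def test_bands_widen_with_level(self):
        tab = noisy_table()
        fit = fit_model(DEPARTURE_SPEC, tab)
        grid = pd.DataFrame([self.scenario()])
        p95 = predict_effects(fit, grid, n_draws=2000, level=0.95, seed=0)
        p50 = predict_effects(fit, grid, n_draws=2000, level=0.50, seed=0)
        assert (p95["cri_hi"] - p95["cri_lo"]).iloc[0] > (p50["cri_hi"] - p50["cri_lo"]).iloc[0]
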