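"""End-to-end orchestration: simulate -> ingest -> depart -> roosts -> covariates -> fit.

A run is driven by a single config (YAML on disk or a :class:`RunConfig`),
executes the stages in order, writes per-stage outputs under the run
directory and finishes with a manifest recording seeds, input hashes and
the row counts at every filter, so identical configs give identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import covariates as cov
from . import departure as dep
from . import inference as inf
from . import roosts as rst
from . import simulate as sim
from .trackio import read_tracks, write_tracks

log = logging.getLogger("dispersalkit")

__all__ = ["RunConfig", "run_all", "run_demo"]


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    departure: dep.DepartureParams = field(default_factory=dep.DepartureParams)
    roosts: rst.RoostParams = field(default_factory=rst.RoostParams)
    n_cri_draws: int = 2000
    n_lrt_sims: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "sim" in raw:
            s = dict(raw["sim"])
            if "hatch_model" in s:
                s["hatch_model"] = sim.HatchModel(**s["hatch_model"])
            if "departure_model" in s:
                s["departure_model"] = sim.DepartureModel(**s["departure_model"])
            kw["sim"] = sim.SimConfig(**s)
        if "departure" in raw:
            kw["departure"] = dep.DepartureParams(**raw["departure"])
        if "roosts" in raw:
            kw["roosts"] = rst.RoostParams(**raw["roosts"])
        for k in ("out_dir", "n_cri_draws", "n_lrt_sims", "seed"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline on a freshly simulated study.

    Returns the run manifest (also written to ``manifest.json``).  Any
    stage failure aborts with the stage named, leaving earlier outputs in
    place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seeds": {"sim": config.sim.seed, "run": config.seed}, "stages": {}}
    stage = "simulate"
    try:
        study = sim.generate_study(config.sim)
        sim.generate_tracks(study, config.sim)
        tracks_path = out / "tracks.csv"
        write_tracks(study.tracks, tracks_path)
        study.juveniles.to_csv(out / "juveniles.csv", index=False)
        sim.truth_report(study).to_csv(out / "truth.csv", index=False)
        manifest["stages"][stage] = {
            "n_broods": int(study.juveniles["brood_id"].nunique()),
            "n_juveniles": int(len(study.juveniles)),
            "n_fixes": len(study.tracks),
            "tracks_sha256": _sha256(tracks_path),
        }

        stage = "ingest"
        tracks = read_tracks(tracks_path)
        manifest["stages"][stage] = {
            "rows_in": tracks.rows_in,
            "rows_kept": tracks.rows_kept,
            "rows_rejected": tracks.rows_rejected,
        }

        stage = "depart"
        results = {}
        rows = []
        for _, ju in study.juveniles.iterrows():
            track = tracks.track(ju["individual_id"])
            res = dep.detect_departure(
                track,
                (ju["nest_lon"], ju["nest_lat"]),
                ju["hatching_date"],
                config.departure,
                individual_id=ju["individual_id"],
            )
            results[ju["individual_id"]] = res
            rows.append(
                {
                    "individual_id": res.individual_id,
                    "status": res.status,
                    "departure_t": res.departure_t,
                    "departure_age_days": res.departure_age_days,
                    "pfdp_days": res.pfdp_days,
                }
            )
        departures = pd.DataFrame(rows)
        departures.to_csv(out / "departures.csv", index=False)
        roster = study.juveniles[["individual_id", "fate"]]
        retained, accounting = dep.apply_exclusions(roster, results)
        manifest["stages"][stage] = accounting

        stage = "roosts"
        roost_sets = {}
        roost_dist = {}
        for yr in sorted(study.juveniles["year"].unique()):
            rs = rst.find_roosts(tracks.fixes, study.study_polygon, int(yr), config.roosts)
            roost_sets[int(yr)] = rs
            rs.centroids.assign(year=yr).to_csv(out / f"roosts_{yr}.csv", index=False)
        for _, ju in study.juveniles.iterrows():
            roost_dist[ju["individual_id"]] = rst.nearest_roost_distance(
                (ju["nest_lon"], ju["nest_lat"]), roost_sets[int(ju["year"])]
            )
        manifest["stages"][stage] = {
            str(yr): len(rs) for yr, rs in roost_sets.items()
        }

        stage = "covariates"
        dens = {}
        for _, ju in study.juveniles.iterrows():
            cents = study.territory_centroids[study.territory_centroids["year"] == ju["year"]]
            dens[ju["individual_id"]] = cov.territory_density(
                (ju["nest_lon"], ju["nest_lat"]), cents, study.study_polygon
            )
        keep = study.juveniles[study.juveniles["individual_id"].isin(retained["individual_id"])]
        table, scaling, rejects = cov.assemble_table(
            keep.drop(columns=["territory_density", "roost_distance_m"]),
            departures,
            densities=pd.Series(dens),
            roost_distances=pd.Series(roost_dist),
        )
        screen = cov.correlation_screen(table)
        table.to_csv(out / "covariates.csv", index=False)
        manifest["stages"][stage] = {
            "n_rows": len(table),
            "n_rejected": len(rejects),
            "high_correlations": screen.to_dict("records"),
        }

        stage = "fit"
        fit = inf.prune_interactions(_spec_with_all_interactions(), table)
        inf.simulate_cri(fit, config.n_cri_draws, seed=config.seed)
        fit_hatch = inf.fit_model(inf.HATCH_SPEC, table)
        inf.simulate_cri(fit_hatch, config.n_cri_draws, seed=config.seed + 1)
        fit_dens = inf.fit_model(inf.DENSITY_SPEC, table)
        fit_roost = inf.fit_model(inf.ROOST_DISTANCE_SPEC, table)
        lrt = inf.random_effect_lrt(
            fit.spec, table, n_null_sims=config.n_lrt_sims, seed=config.seed + 2
        )
        path = inf.path_analysis(fit_hatch, fit, seed=config.seed + 3, scaling=scaling)
        fits = {
            "departure": _fit_to_dict(fit),
            "hatching_date": _fit_to_dict(fit_hatch),
            "territory_density": _fit_to_dict(fit_dens),
            "roost_distance": _fit_to_dict(fit_roost),
            "random_effect_lrt": {"statistic": lrt["statistic"], "p": lrt["p"]},
            "path": {
                "indirect": path.indirect,
                "direct": path.direct,
                "natural": path.natural,
                "intervals": path.intervals.to_dict("index"),
            },
        }
        (out / "fits.json").write_text(json.dumps(fits, indent=2, default=float))
        manifest["stages"][stage] = {
            "departure_coefficients": fit.params.to_dict(),
            "pruning_steps": len(fit.pruning_trace),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    log.info("pipeline finished; manifest at %s", manifest_path)
    return manifest


def _spec_with_all_interactions() -> inf.ModelSpec:
    """Departure spec with the candidate two-way interactions to prune."""
    base = inf.DEPARTURE_SPEC
    candidates = (
        "treatment:elevation_m",
        "treatment:hatching_doy",
        "C(year):territory_density",
        "sex:territory_density",
        "sex:elevation_m",
        "hatching_doy:elevation_m",
    )
    return inf.ModelSpec(base.response, base.fixed, candidates, base.group, base.reml)


def _fit_to_dict(fit: inf.ModelFit) -> dict:
    return {
        "coefficients": fit.coef_table.reset_index().rename(columns={"index": "term"}).to_dict("records"),
        "re_sd": fit.re_sd,
        "resid_sd": fit.resid_sd,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
    }


def run_demo(out_dir: str = "demo_out", seed: int = 0) -> dict:
    """Generate and analyse a bundled synthetic study end-to-end."""
    config = RunConfig(
        out_dir=out_dir,
        sim=sim.SimConfig(seed=seed),
        n_cri_draws=2000,
        n_lrt_sims=100,
        seed=seed,
    )
    return run_all(config)
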