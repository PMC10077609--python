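"""End-to-end pipeline: simulate → operationalize → fit → select → smooth → access.

Every run is a pure function of its configuration: all artifacts carry the
config hash and seed, and re-running the same config yields byte-identical
outputs. The run log records the count at every filter stage (the
identification/exclusion funnel) and each stage's output feeds the next.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import fileio
from .accessibility import FacilitySet, Facility, ScenarioSpec, run_scenarios
from .closure_model import RegressionSpec, backward_stepwise_aic, fit_logistic, lowess_curve
from .fileio import PipelineConfig
from .operationalize import (
    apply_exclusions,
    build_closure_cohort,
    cohort_frame,
    funnel_statistics,
    identify_obstetric_sites,
)
from .synthetic_region import (
    RegionConfig,
    final_model_preset,
    generate_network,
    place_hospitals,
    simulate_closures,
)

logger = logging.getLogger("obstaccess")

STAGES = ("simulate", "cohort", "fit", "smooth", "access", "report")


def config_hash(config: PipelineConfig) -> str:
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()}
    data["scenarios"] = [dict(s) for s in config.scenarios]
    return hashlib.sha256(json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the pipeline and persist artifacts under ``outdir``.

    Stages listed in ``stages`` write their artifacts; earlier stages always
    execute in memory (they are cheap and deterministic) so any requested
    stage has its inputs. A failing stage aborts with its name; the partial
    run log is persisted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
        "counts": {},
    }
    stage = "setup"
    try:
        # ---- simulate or load inputs ------------------------------------
        stage = "simulate"
        if config.simulate:
            region_cfg = RegionConfig(
                n_sites=config.n_sites, n_nodes=config.n_nodes, seed=config.seed
            )
            network = generate_network(region_cfg)
            baseline_full, areas_df = place_hospitals(network, region_cfg)
            areas = {
                str(r["postal_area"]): (float(r["density_raw"]), float(r["fertility_rate"]))
                for _, r in areas_df.iterrows()
            }
            baseline_obs = identify_obstetric_sites(baseline_full)
            pre_cohort = build_closure_cohort(
                baseline_obs, baseline_obs, areas, network=network
            )
            covariates = cohort_frame(pre_cohort)
            closed, followup_full = simulate_closures(
                baseline_obs, covariates, final_model_preset(), seed=config.seed
            )
            logger.info("simulated %d sites, %d closures", len(baseline_obs), int(closed.sum()))
            if "simulate" in stages:
                fileio.write_registry(baseline_full, outdir / "registry_baseline.csv")
                fileio.write_registry(followup_full, outdir / "registry_followup.csv")
                fileio.write_areas(areas, outdir / "areas.csv")
                fileio.write_network_csv(
                    network, outdir / "network_nodes.csv", outdir / "network_edges.csv"
                )
                fileio.write_network_geojson(network, outdir / "network.geojson")
        else:
            baseline_full = fileio.read_registry(config.registry_baseline)
            followup_full = fileio.read_registry(config.registry_followup)
            areas = fileio.read_areas(config.areas)
            network = (
                fileio.read_network_csv(config.network_nodes, config.network_edges)
                if config.network_nodes
                else None
            )
        run_log["counts"]["baseline_records"] = len(baseline_full)
        run_log["counts"]["followup_records"] = len(followup_full)
        run_log["stages"]["simulate"] = "ok"

        # ---- operationalize ---------------------------------------------
        stage = "cohort"
        baseline_obs = identify_obstetric_sites(baseline_full)
        followup_obs = identify_obstetric_sites(followup_full)
        logger.info(
            "identified obstetric sites: baseline %d, follow-up %d",
            len(baseline_obs),
            len(followup_obs),
        )
        cohort = build_closure_cohort(
            baseline_obs,
            followup_obs,
            areas,
            network=network,
            followup_full_registry=followup_full,
        )
        regression_cohort, exclusion_log = apply_exclusions(cohort)
        logger.info("exclusions: %s", exclusion_log)
        funnel = funnel_statistics(
            baseline_obs, followup_obs, cohort, regression_cohort, exclusion_log
        )
        run_log["counts"]["baseline_obstetric"] = len(baseline_obs)
        run_log["counts"]["followup_obstetric"] = len(followup_obs)
        run_log["counts"]["cohort_rows"] = len(cohort)
        run_log["counts"].update(
            {f"exclusion_{k}": v for k, v in exclusion_log.items()}
        )
        if "cohort" in stages:
            fileio.write_cohort(cohort, outdir / "cohort.csv")
            fileio.write_cohort(regression_cohort, outdir / "cohort_regression.csv")
            (outdir / "exclusion_log.json").write_text(
                json.dumps(exclusion_log, sort_keys=True, indent=2)
            )
            (outdir / "funnel.json").write_text(json.dumps(funnel, sort_keys=True, indent=2))
        run_log["stages"]["cohort"] = "ok"

        # ---- regression + selection --------------------------------------
        stage = "fit"
        frame = cohort_frame(regression_cohort)
        spec = RegressionSpec()
        full = fit_logistic(frame, spec)
        final, trace = backward_stepwise_aic(frame, spec)
        if "fit" in stages:
            fileio.write_regression_table(full, outdir / "model_full.csv")
            fileio.write_regression_table(final, outdir / "model_final.csv")
            import pandas as pd

            pd.DataFrame(trace).to_csv(outdir / "stepwise_trace.csv", index=False)
        run_log["counts"]["regression_n"] = full.n_obs
        run_log["stages"]["fit"] = "ok"

        # ---- LOWESS -------------------------------------------------------
        stage = "smooth"
        curves = lowess_curve(frame, stratify_by_pediatrics=True)
        if "smooth" in stages or "fit" in stages:
            import pandas as pd

            rows = []
            for name, c in curves.items():
                for x, y in zip(c.x, c.y):
                    rows.append({"stratum": name, "live_births": x, "closure_probability": y})
            pd.DataFrame(rows).to_csv(outdir / "lowess_curves.csv", index=False)
        run_log["stages"]["smooth"] = "ok"

        # ---- accessibility ------------------------------------------------
        stage = "access"
        if network is None:
            raise RuntimeError("accessibility stage requires a road network")
        facilities = FacilitySet(
            tuple(
                Facility(r.site_id, r.location, r.live_births, r.has_pediatrics)
                for r in cohort
                if not r.closed_by_followup
            )
        )
        scenarios = tuple(
            ScenarioSpec(
                name=s["name"],
                require_pediatrics=bool(s.get("require_pediatrics", False)),
                min_live_births=s.get("min_live_births"),
            )
            for s in config.scenarios
        )
        surfaces, coverage = run_scenarios(
            network,
            facilities,
            scenarios,
            n_points=config.sampler_n,
            seed=config.seed,
            thresholds=config.thresholds,
        )
        if "access" in stages:
            coverage.fractions.to_csv(outdir / "coverage.csv", index=False)
            if coverage.deltas is not None:
                coverage.deltas.to_csv(outdir / "coverage_deltas.csv", index=False)
            coverage_json = {
                "fractions": coverage.fractions.to_dict(orient="records"),
                "deltas": (
                    coverage.deltas.to_dict(orient="records")
                    if coverage.deltas is not None
                    else None
                ),
            }
            (outdir / "coverage.json").write_text(
                json.dumps(coverage_json, sort_keys=True, indent=2)
            )
            for name, surf in surfaces.items():
                surf.points.to_csv(outdir / f"surface_{name}.csv", index=False)
        run_log["counts"]["active_facilities"] = len(facilities)
        run_log["counts"]["sampled_points"] = config.sampler_n
        run_log["stages"]["access"] = "ok"

        run_log["funnel"] = funnel
    except Exception as exc:
        run_log["failed_stage"] = stage
        run_log["error"] = str(exc)
        (outdir / "run_log.json").write_text(_dump_log(run_log))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.json").write_text(_dump_log(run_log))
    return run_log


def _dump_log(run_log: dict) -> str:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    return json.dumps(run_log, sort_keys=True, indent=2, default=_default)
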