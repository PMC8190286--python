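"""End-to-end pipeline: ingest -> events -> rates -> vigilance -> activity
-> occupancy, with a single JSON report mirroring the analysis' result
sections and a provenance block (config hash, seed, version).

All stages write their tabular outputs as CSV/JSON files first; the report
aggregates them.  Re-running on identical inputs, config, and seed
reproduces the report byte-for-byte (no wall-clock timestamps are hashed
or embedded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import activity as activity_mod
from . import events as events_mod
from . import occupancy as occupancy_mod
from . import rates as rates_mod
from . import vigilance as vigilance_mod
from .core_io import (
    AnalysisConfig,
    join_snow,
    read_detections,
    read_operability,
    read_snow,
)

logger = logging.getLogger(__name__)

SUBORDINATE = "marten"
DOMINANT = "fisher"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    return obj


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    detections_path: str | Path,
    snow_path: str | Path,
    operability_path: str | Path,
    config: AnalysisConfig | None = None,
    outdir: str | Path = "scavcam_out",
    make_plots: bool = False,
) -> dict:
    """Execute every analysis stage and write module outputs plus report.json.

    Degenerate inputs degrade gracefully: with no dominant-species records
    the displacement and overlap sections are marked absent and every
    vigilance use class is NO_USE.  A manifest of completed stages is kept
    so partial output is interpretable if a stage raises.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.rng_seed,
        },
        "sections": {},
    }

    def finish_stage(name: str) -> None:
        manifest.append(name)
        (outdir / "manifest.json").write_text(json.dumps({"completed_stages": manifest}, indent=2))

    try:
        detections, validation = read_detections(detections_path)
        snow = read_snow(snow_path)
        operability_tbl = read_operability(operability_path)
        report["sections"]["ingest"] = {
            "n_detections": int(len(detections)),
            "n_flagged": validation.n_flagged,
        }
        finish_stage("ingest")

        # --- events ---
        visits = events_mod.segment_visits(detections, config.independence_gap_min)
        visits_out = visits.drop(columns=["image_ids"]).copy()
        for col in ("start", "end"):
            visits_out[col] = pd.to_datetime(visits_out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        visits_out.to_csv(outdir / "visits.csv", index=False)
        disp = events_mod.detect_displacements(
            detections, config.displacement_window_min, config.independence_gap_min
        )
        disp_out = disp.copy()
        for col in ("last_displaced_time", "first_displacer_time"):
            disp_out[col] = pd.to_datetime(disp_out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        disp_out.to_csv(outdir / "displacements.csv", index=False)
        hist = events_mod.peri_event_histogram(
            detections[detections["species"] == SUBORDINATE],
            detections[detections["species"] == DOMINANT],
            bin_min=config.histogram_bin_min,
            halfwidth_min=config.histogram_halfwidth_min,
            gap_min=config.independence_gap_min,
            convention=config.histogram_convention,
        )
        hist.to_frame().to_csv(outdir / "peri_event_histogram.csv", index=False)
        if make_plots:
            from .plots import plot_peri_event_histogram

            plot_peri_event_histogram(hist, outdir / "peri_event_histogram.png")
        n_visits = visits.groupby("species").size().to_dict()
        report["sections"]["events"] = {
            "n_visits": {k: int(v) for k, v in n_visits.items()},
            "n_displacements": int(len(disp)),
            "histogram_reference_events": hist.n_reference_events,
        }
        finish_stage("events")

        # --- rates ---
        n_sub = int(n_visits.get(SUBORDINATE, 0))
        n_dom = int(n_visits.get(DOMINANT, 0))
        x_sub = int((disp["displaced_species"] == SUBORDINATE).sum())
        x_dom = int((disp["displaced_species"] == DOMINANT).sum())
        rates_section: dict = {"absent": False}
        if n_sub and n_dom:
            comparison = rates_mod.compare_rates(
                x_sub, n_sub, x_dom, n_dom, conf=config.conf_level, seed=config.rng_seed
            )
            rates_section.update(
                {
                    "subordinate_displaced": _jsonable(comparison.estimate_1)
                    | {"reciprocal": comparison.estimate_1.reciprocal},
                    "dominant_displaced": _jsonable(comparison.estimate_2)
                    | {"reciprocal": comparison.estimate_2.reciprocal},
                    "p_fisher_one_sided": comparison.p_fisher_one_sided,
                    "p_posterior_rate2_ge_rate1": comparison.p_posterior,
                    "direction": comparison.direction,
                }
            )
        elif n_sub:
            est = rates_mod.rate_estimate(x_sub, n_sub, config.conf_level)
            rates_section.update(
                {"subordinate_displaced": _jsonable(est) | {"reciprocal": est.reciprocal}}
            )
        else:
            rates_section["absent"] = True
        (outdir / "rates.json").write_text(json.dumps(_jsonable(rates_section), indent=2, sort_keys=True))
        report["sections"]["rates"] = rates_section
        finish_stage("rates")

        # --- vigilance ---
        det_snow = join_snow(detections, snow)
        vig_section = {}
        for focal, other in ((SUBORDINATE, DOMINANT), (DOMINANT, SUBORDINATE)):
            if not (detections["species"] == focal).any():
                vig_section[focal] = {"absent": True}
                continue
            obs, median_used = vigilance_mod.build_observations(
                det_snow,
                focal,
                other,
                analysis_start=config.analysis_start,
                window_h=config.recent_use_window_h,
            )
            entry: dict = {
                "absent": False,
                "n_observations": int(len(obs)),
                "median_threshold": median_used,
                "use_class_counts": obs["use_class"].value_counts().to_dict(),
                "vigilant_share": float(obs["vigilant"].mean()) if len(obs) else None,
            }
            try:
                fit = vigilance_mod.fit_vigilance_model(obs)
                entry["model"] = fit.table.to_dict(orient="records")
                entry["sigma_year"] = fit.sigma_year
                entry["dropped_levels"] = fit.dropped_levels
                fit.table.to_csv(outdir / f"vigilance_{focal}.csv", index=False)
            except vigilance_mod.ConvergenceError as err:
                entry["model_error"] = str(err)
            vig_section[focal] = entry
        report["sections"]["vigilance"] = vig_section
        finish_stage("vigilance")

        # --- activity ---
        used, not_used = activity_mod.split_by_prior_use(
            detections, SUBORDINATE, DOMINANT, config.analysis_start
        )
        from .core_io import filter_after_analysis_start

        dom_det = filter_after_analysis_start(
            detections[detections["species"] == DOMINANT], config.analysis_start
        )
        dom_times = activity_mod.timestamps_to_radians(dom_det["timestamp"]) if len(dom_det) else np.array([])
        comp = activity_mod.activity_comparison(
            used, not_used, dom_times, n_boot=config.bootstrap_iterations,
            seed=config.rng_seed, conf=config.conf_level,
        )
        dens_frames = []
        for label, d in comp["densities"].items():
            dens_frames.append(pd.DataFrame({"grid_radians": d.grid, f"density_{label}": d.density}).set_index("grid_radians"))
        if dens_frames:
            pd.concat(dens_frames, axis=1).reset_index().to_csv(outdir / "activity_densities.csv", index=False)
        if make_plots and comp["densities"]:
            from .plots import plot_activity_densities

            plot_activity_densities(comp["densities"], outdir / "activity_densities.png")
        overlaps = {k: _jsonable(v) for k, v in comp["overlaps"].items()}
        (outdir / "overlaps.json").write_text(json.dumps(overlaps, indent=2, sort_keys=True))
        report["sections"]["activity"] = {
            "absent": len(comp["overlaps"]) == 0,
            "n_images": {
                "marten_used": int(len(used)),
                "marten_not_used": int(len(not_used)),
                "fisher": int(len(dom_times)),
            },
            "overlaps": overlaps,
        }
        finish_stage("activity")

        # --- occupancy ---
        cooc_pooled = occupancy_mod.cooccupancy(visits, SUBORDINATE, DOMINANT, "pooled")
        cooc_winter = occupancy_mod.cooccupancy(visits, SUBORDINATE, DOMINANT, "per_winter")
        pairs = occupancy_mod.pair_visit_stats(visits, detections, SUBORDINATE)
        oper = occupancy_mod.operability(operability_tbl)
        occ_section = {
            "cooccupancy_pooled": _jsonable(cooc_pooled[0]),
            "cooccupancy_per_winter": [_jsonable(c) for c in cooc_winter],
            "pair_visits": _jsonable(pairs),
            "operability": _jsonable(oper),
        }
        (outdir / "occupancy.json").write_text(json.dumps(_jsonable(occ_section), indent=2, sort_keys=True))
        report["sections"]["occupancy"] = occ_section
        finish_stage("occupancy")
    except Exception:
        (outdir / "manifest.json").write_text(json.dumps({"completed_stages": manifest}, indent=2))
        raise

    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(payload)
    return report


def simulate_and_check(sim_config=None, outdir: str | Path = "scavcam_sim", n_boot: int = 200) -> dict:
    """Generate a synthetic study, write its files, and run the recovery report."""
    from .simulate import SimConfig, config_to_dict, recover_all, simulate_study

    sim_config = sim_config or SimConfig()
    outdir = Path(outdir)
    sim = simulate_study(sim_config)
    sim.write(outdir)
    analysis = AnalysisConfig(rng_seed=sim_config.rng_seed, bootstrap_iterations=max(n_boot, 100))
    report = recover_all(sim, analysis, n_boot=n_boot)
    if n_boot < 100:
        report["warnings"] = [f"bootstrap iterations reduced to {n_boot} (< 100): CIs unstable"]
    serializable = {
        "config": config_to_dict(sim_config),
        "checks": report["checks"],
        "n_passed": report["n_passed"],
        "n_checks": report["n_checks"],
        "all_passed": report["all_passed"],
    }
    if "warnings" in report:
        serializable["warnings"] = report["warnings"]
    (outdir / "recovery.json").write_text(json.dumps(_jsonable(serializable), indent=2, sort_keys=True))
    return report
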