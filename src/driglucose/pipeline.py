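"""Pipeline runner: simulate -> isochrones -> exposure -> index -> map -> validate.

Each stage writes its outputs plus a checksummed manifest into the run
directory; a failing stage aborts the run, leaves partial outputs behind and
drops a ``FAILED`` marker naming the stage and cause. One master seed
deterministically derives every stage's randomness.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .exposure import CensusAreaSet, exposure_profile, profiles_to_frame
from .index import DiabetesRiskIndex
from .io_utils import GridSpec, Manifest, read_asc, write_asc
from .network import SnapError, StreetNetwork, WalkProfile, compute_ring_set, write_ring_set
from .surface import map_index
from .synthetic import Scenario, ScenarioConfig, simulate_scenario, write_scenario
from .validation import DiabetesModelSuite

log = logging.getLogger("driglucose")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scenario_config(cfg: RunConfig) -> ScenarioConfig:
    return ScenarioConfig(
        extent=(0.0, 0.0, cfg.extent_m, cfg.extent_m),
        street_spacing=cfg.street_spacing,
        street_irregularity=cfg.street_irregularity,
        n_census_areas=cfg.n_census_areas,
        ses_spatial_range=cfg.ses_spatial_range,
        ndvi_smoothness=cfg.ndvi_smoothness,
        ndvi_ses_coupling=cfg.ndvi_ses_coupling,
        n_participants=cfg.n_participants,
        true_index_log_or=cfg.true_index_log_or,
        target_prevalence=cfg.target_prevalence,
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages in order; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.json").write_text(json.dumps(cfg.echo(), indent=2, default=str))
    state: dict = {}
    stage = "setup"
    stage_order = ("simulate", "isochrones", "exposure", "index", "map", "validate")
    try:
        for stage in stage_order:
            if stage in cfg.stages:
                log.info("running stage %s", stage)
                _STAGES[stage](cfg, out, state)
    except Exception as err:  # noqa: BLE001 - partial outputs must be marked
        (out / "FAILED").write_text(f"{getattr(err, 'stage', 'unknown')}: {err}\n")
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err
    return out


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = simulate_scenario(_scenario_config(cfg))
    paths = write_scenario(scenario, out)
    manifest = Manifest(stage="simulate", config_echo=cfg.echo())
    for p in paths.values():
        manifest.add(p)
    manifest.write(out / "manifest_simulate.json")
    state["scenario"] = scenario


def load_scenario(in_dir: str | Path, cfg: RunConfig) -> Scenario:
    """Read a previously written (or externally prepared) scenario directory.

    Expects the text layers ``write_scenario`` produces: network_edges.csv,
    census_areas.geojson + census_attributes.csv, ndvi.asc, cohort.csv.
    """
    in_dir = Path(in_dir)
    network = StreetNetwork.from_edge_csv(in_dir / "network_edges.csv")
    areas = CensusAreaSet.read(
        in_dir / "census_areas.geojson", in_dir / "census_attributes.csv"
    )
    ndvi = read_asc(in_dir / "ndvi.asc")
    cohort = pd.read_csv(in_dir / "cohort.csv")
    return Scenario(config=_scenario_config(cfg), network=network, areas=areas,
                    ndvi=ndvi, cohort=cohort)


def _require_scenario(cfg: RunConfig, state: dict):
    if "scenario" not in state:
        if cfg.input_dir:
            state["scenario"] = load_scenario(cfg.input_dir, cfg)
        else:
            raise FileNotFoundError(
                "no scenario in run state; enable the simulate stage or set input_dir"
            )
    return state["scenario"]


def _stage_isochrones(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = _require_scenario(cfg, state)
    cohort = scenario.cohort
    ring_sets, flagged = {}, []
    for row in cohort.itertuples():
        profile = WalkProfile(age=float(row.age), sex=str(row.sex))
        try:
            ring_sets[row.participant_id] = compute_ring_set(
                scenario.network,
                (row.x, row.y),
                profile,
                increment_min=cfg.increment_min,
                max_time_min=cfg.max_time_min,
                buffer_m=cfg.buffer_m,
                max_snap_m=cfg.max_snap_m,
            )
        except SnapError as err:
            flagged.append({"participant_id": row.participant_id, "reason": str(err)})
    state["ring_sets"] = ring_sets
    state["snap_flags"] = flagged
    manifest = Manifest(stage="isochrones", config_echo=cfg.echo())
    sample_id = next(iter(ring_sets), None)
    if sample_id is not None:
        sample_path = out / "rings_sample.geojson"
        write_ring_set(ring_sets[sample_id], sample_path)
        manifest.add(sample_path)
    flag_path = out / "snap_flags.json"
    flag_path.write_text(json.dumps(flagged, indent=2, default=str))
    manifest.add(flag_path)
    manifest.write(out / "manifest_isochrones.json")


def _stage_exposure(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = _require_scenario(cfg, state)
    if "ring_sets" not in state:
        raise FileNotFoundError("exposure stage needs the isochrones stage")
    profiles = [
        exposure_profile(
            rings, scenario.areas, scenario.ndvi,
            steepness_b=cfg.logit_b, midpoint_m=cfg.logit_m, location_id=pid,
        )
        for pid, rings in state["ring_sets"].items()
    ]
    frame = profiles_to_frame(profiles)
    path = out / "exposure_profiles.csv"
    frame.to_csv(path)
    state["profiles"] = frame
    manifest = Manifest(stage="exposure", config_echo=cfg.echo())
    manifest.add(path)
    manifest.write(out / "manifest_exposure.json")


def _stage_index(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = _require_scenario(cfg, state)
    if "profiles" not in state:
        raise FileNotFoundError("index stage needs the exposure stage")
    frame = state["profiles"]
    cohort = scenario.cohort.set_index("participant_id")
    labels = cohort.loc[frame.index, "diabetes"].to_numpy()
    model = DiabetesRiskIndex(frame, labels, variant=cfg.variant).fit(
        n_iterations=cfg.n_iterations, seed=cfg.seed, drop_threshold=cfg.drop_threshold
    )
    path = out / "index_model.txt"
    model.save(path)
    (out / "index_summary.txt").write_text(model.summary() + "\n")
    scores = model.score(frame)
    score_path = out / "index_scores.csv"
    pd.DataFrame({"participant_id": frame.index, "index_score": scores}).to_csv(
        score_path, index=False
    )
    state["index_model"] = model
    state["index_scores"] = pd.Series(scores, index=frame.index)
    manifest = Manifest(stage="index", config_echo=cfg.echo())
    manifest.add(path)
    manifest.add(score_path)
    manifest.write(out / "manifest_index.json")


def _stage_map(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = _require_scenario(cfg, state)
    if "index_model" not in state:
        raise FileNotFoundError("map stage needs the index stage")
    grid = GridSpec.from_bounds(scenario.config.extent, cfg.grid_m)
    surface = map_index(
        grid,
        scenario.network,
        scenario.areas,
        scenario.ndvi,
        state["index_model"],
        speed_kmh=cfg.speed_kmh,
        increment_min=cfg.increment_min,
        max_time_min=cfg.max_time_min,
        buffer_m=cfg.buffer_m,
        max_snap_m=cfg.max_snap_m,
        logit_b=cfg.logit_b,
        logit_m=cfg.logit_m,
    )
    asc_path = out / "risk_surface.asc"
    write_asc(surface.raster, asc_path)
    report_path = out / "surface_report.json"
    report_path.write_text(json.dumps(surface.run_report(), indent=2, default=str))
    # rendering-ready colour ramp: low risk (light) -> high risk (dark)
    ramp_path = out / "risk_surface_ramp.txt"
    ramp_path.write_text(
        "value,red,green,blue\n-1,255,255,229\n-0.5,199,233,180\n0,127,205,187\n"
        "0.5,44,127,184\n1,8,29,88\n"
    )
    state["surface"] = surface
    manifest = Manifest(stage="map", config_echo=cfg.echo())
    for p in (asc_path, report_path, ramp_path):
        manifest.add(p)
    manifest.write(out / "manifest_map.json")


def _stage_validate(cfg: RunConfig, out: Path, state: dict) -> None:
    scenario = _require_scenario(cfg, state)
    if "index_scores" not in state:
        raise FileNotFoundError("validate stage needs the index stage")
    scores = state["index_scores"]
    cohort = scenario.cohort.set_index("participant_id").loc[scores.index].reset_index()
    suite = DiabetesModelSuite(cohort, scores.to_numpy())
    report = suite.fit(seed=cfg.seed, test_fraction=cfg.test_fraction, k=cfg.cv_folds)
    text_path = out / "validation_report.txt"
    text_path.write_text(report.summary() + "\n")
    tables = []
    for label, table in (("semi_adjusted", report.semi_adjusted),
                         ("fully_adjusted", report.fully_adjusted)):
        if table is not None:
            t = table.copy()
            t.insert(0, "model", label)
            tables.append(t)
    manifest = Manifest(stage="validate", config_echo=cfg.echo())
    if tables:
        coef_path = out / "validation_coefficients.csv"
        pd.concat(tables).to_csv(coef_path)
        manifest.add(coef_path)
    state["validation"] = report
    manifest.add(text_path)
    manifest.write(out / "manifest_validate.json")


_STAGES = {
    "simulate": _stage_simulate,
    "isochrones": _stage_isochrones,
    "exposure": _stage_exposure,
    "index": _stage_index,
    "map": _stage_map,
    "validate": _stage_validate,
}


def demo_config(out_dir: str = "demo_run", seed: int = 0) -> RunConfig:
    """Small packaged scenario exercising the full pipeline in minutes."""
    return RunConfig(
        extent_m=1500.0,
        street_spacing=120.0,
        street_irregularity=0.25,
        n_census_areas=40,
        ses_spatial_range=400.0,
        ndvi_smoothness=150.0,
        n_participants=220,
        grid_m=150.0,
        cv_folds=5,
        seed=seed,
        out_dir=out_dir,
    )
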