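"""End-to-end pipeline orchestration.

Runs the full analysis in order — tracks → preprocessing/filtering →
moving-window cross-correlation → net-probability maps → model grid search
and simulation → metastable-subpopulation detection — and writes each
stage's artifact into a run directory.  Every randomized stage draws its
seed deterministically from the single master seed, so a run is bit-stable:
the same config and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import crosscorr, io, modelselect, preprocess, probmaps, simulate, subpops
from .synthetic import CohortConfig, default_plastic_config, generate_cohort

logger = logging.getLogger(__name__)

#: Core artifact files written by every successful run.
ARTIFACTS = (
    "observations.csv",
    "map_area.csv",
    "map_tension.csv",
    "map_lag.csv",
    "simulation_summary.json",
    "selection_report.json",
    "subpopulations.json",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Run configuration (desk-scale defaults).

    ``input_table`` points at an existing track-table CSV; when ``None`` a
    synthetic cohort is generated from ``cohort`` (seeded from the master
    ``seed``).  The simulator grid lists default to a small search around
    the canonical values so a full run stays in the minutes range.
    """

    sampling_interval: float = 30.0          # seconds
    smoothing_p: float = preprocess.DEFAULT_SMOOTHING_P
    window_len: int = crosscorr.DEFAULT_WINDOW_LEN
    step: int = 1
    r_threshold: float = crosscorr.DEFAULT_R_THRESHOLD
    min_lifetime: int = preprocess.MIN_LIFETIME
    min_area_range: float = preprocess.MIN_AREA_RANGE
    area_grid: tuple = probmaps.DEFAULT_AREA_GRID
    bandwidths: tuple | None = None          # None → Silverman per axis
    density_floor: float = probmaps.DEFAULT_DENSITY_FLOOR
    # simulator model grid (six value lists)
    mu1_list: tuple = (0.001, 0.005, 0.0075)
    mu2_list: tuple = (0.025, 0.05, 0.1)
    nu_list: tuple = (0.125, 0.25)
    tau1_list: tuple = (5,)
    tau2_list: tuple = (3,)
    tau3_list: tuple = (3,)
    n_traj: int = 200
    max_iter: int = simulate.MAX_ITERATIONS
    # subpopulations
    stable_tol: float = 0.0
    k_max: int = 5
    gmm_repeats: int = 30
    input_table: str | None = None
    cohort: CohortConfig = field(default_factory=default_plastic_config)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        for name in ("r_threshold", "min_area_range", "density_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stage_seeds(self) -> dict:
        s = np.random.SeedSequence(self.seed).generate_state(3)
        return {"generate": int(s[0]) % (2 ** 31), "simulate": int(s[1]) % (2 ** 31),
                "subpops": int(s[2]) % (2 ** 31)}


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", None)
    cfg = PipelineConfig(**raw)
    if cohort_raw is not None:
        lag_raw = cohort_raw.pop("lag_rule", None)
        bands = cohort_raw.pop("coupling_bands", None)
        cohort = CohortConfig(**cohort_raw)
        if lag_raw is not None:
            from .synthetic import LagRule
            cohort.lag_rule = LagRule(**lag_raw)
        if bands is not None:
            cohort.coupling_bands = tuple(tuple(b) for b in bands)
        cfg.cohort = cohort
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage and write artifacts into ``out_dir``.

    Returns the run directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    stage = "load"
    try:
        # --- tracks ---------------------------------------------------
        if config.input_table is not None:
            table = io.read_track_table(config.input_table)
        else:
            stage = "generate"
            table = generate_cohort(config.cohort, seed=seeds["generate"])
        io.write_track_table(table, out / "tracks.csv")
        logger.info("tracks: %d rows, %d tracks", len(table), table.n_tracks)

        # --- preprocess -----------------------------------------------
        stage = "preprocess"
        smoothing = preprocess.SmoothingConfig(p=config.smoothing_p)
        tracks = preprocess.filter_tracks(
            preprocess.process_table(table, smoothing),
            min_lifetime=config.min_lifetime,
            min_area_range=config.min_area_range)
        if not tracks:
            raise PipelineError("preprocess: zero tracks retained by the filters")
        preprocess.processed_to_frame(tracks).to_csv(
            out / "processed_tracks.csv", index=False, float_format="%.17g")
        logger.info("preprocess: retained %d tracks", len(tracks))

        # --- cross-correlation ----------------------------------------
        stage = "xcorr"
        observations = crosscorr.extract_all(
            tracks, window_len=config.window_len, step=config.step,
            r_threshold=config.r_threshold)
        if not observations:
            raise PipelineError("xcorr: no significant windows found")
        crosscorr.observations_to_frame(observations).to_csv(
            out / "observations.csv", index=False, float_format="%.17g")
        logger.info("xcorr: %d significant windows", len(observations))

        # --- maps ------------------------------------------------------
        stage = "maps"
        area_map = probmaps.sign_probability_map(
            observations, "area", grid=config.area_grid,
            bandwidths=config.bandwidths, density_floor=config.density_floor)
        tension_map = probmaps.sign_probability_map(
            observations, "tension", bandwidths=config.bandwidths,
            density_floor=config.density_floor)
        lag_map = probmaps.lag_ordering_map(
            observations, grid=config.area_grid,
            bandwidths=config.bandwidths, density_floor=config.density_floor)
        probmaps.write_map(area_map, out / "map_area.csv")
        probmaps.write_map(tension_map, out / "map_tension.csv")
        probmaps.write_map(lag_map, out / "map_lag.csv")

        # --- model selection ------------------------------------------
        stage = "grid-search"
        grid = modelselect.build_parameter_grid(
            config.mu1_list, config.mu2_list, config.nu_list,
            config.tau1_list, config.tau2_list, config.tau3_list)
        empirical = modelselect.features_from_processed(tracks)
        results = modelselect.grid_search(
            grid, empirical, area_map, tension_map,
            n_traj=config.n_traj, seed=seeds["simulate"],
            max_iter=config.max_iter)
        modelselect.results_to_frame(results).to_csv(
            out / "selection_leaderboard.csv", index=False, float_format="%.17g")
        best = modelselect.best_models(results)
        report = {
            "n_models": len(grid),
            "objectives": {
                name: {
                    "params": dataclasses.asdict(res.params),
                    "chi2": res.chi2,
                    "score": res.scores[name],
                }
                for name, res in best.items()
            },
        }
        _write_json(report, out / "selection_report.json")
        logger.info("grid-search: %d models scored", len(grid))

        # --- simulation of the selected model -------------------------
        stage = "simulate"
        best_all = best["all"].params
        trajectories, freqs = simulate.simulate_population(
            area_map, tension_map, best_all, n=config.n_traj,
            seed=seeds["simulate"], max_iter=config.max_iter)
        lifetimes = [tr.lifetime for tr in trajectories]
        _write_json({
            "params": dataclasses.asdict(best_all),
            "objective": "all",
            "n_trajectories": len(trajectories),
            "termination_frequencies": freqs,
            "median_lifetime": float(np.median(lifetimes)),
            "seed": seeds["simulate"],
        }, out / "simulation_summary.json")
        logger.info("simulate: termination frequencies %s", freqs)

        # --- subpopulations -------------------------------------------
        stage = "subpops"
        emp_stable = subpops.stable_areas_empirical(tracks, tol=config.stable_tol)
        syn_stable = subpops.stable_areas_synthetic(trajectories)
        sub_report = {"empirical": {"n_stable_events": int(emp_stable.size)},
                      "synthetic": {"n_type_iv": int(syn_stable.size)}}
        if emp_stable.size >= 3 * config.k_max:
            modal_k, chosen, fits = subpops.select_k_by_aic(
                emp_stable, k_max=config.k_max, repeats=config.gmm_repeats,
                seed=seeds["subpops"])
            sub_report["empirical"] |= {
                "modal_k": modal_k,
                "chosen_k_counts": {int(k): int(c) for k, c in
                                    zip(*np.unique(chosen, return_counts=True))},
                "pooled_means": sorted(subpops.pooled_subpopulation_means(fits)),
            }
        if syn_stable.size >= 3 * config.k_max:
            modal_k, chosen, fits = subpops.select_k_by_aic(
                syn_stable, k_max=config.k_max, repeats=config.gmm_repeats,
                seed=seeds["subpops"] + 1)
            sub_report["synthetic"] |= {
                "modal_k": modal_k,
                "chosen_k_counts": {int(k): int(c) for k, c in
                                    zip(*np.unique(chosen, return_counts=True))},
                "pooled_means": sorted(subpops.pooled_subpopulation_means(fits)),
            }
        _write_json(sub_report, out / "subpopulations.json")

        # --- manifest --------------------------------------------------
        stage = "manifest"
        manifest = {"config": _config_dict(config), "stage_seeds": seeds,
                    "n_tracks": table.n_tracks, "n_retained": len(tracks),
                    "n_observations": len(observations)}
        _write_json(manifest, out / "manifest.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
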