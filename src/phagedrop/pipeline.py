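"""End-to-end workflow: simulate -> render -> analyze-images ->
analyze-growth, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .growth import cohort_summary
from .io import (
    ExperimentConfig,
    load_stack,
    read_rois_csv,
    read_trajectory_csv,
    save_stack,
    write_rois_csv,
    write_trajectory_csv,
)
from .images import build_shading_corrector, extract_trajectories
from .params import PHAGE_PRESETS, OpticsParams, ShadingFieldSpec, SimParams
from .render import droplet_rois, render_flatfield, render_stack
from .simulate import simulate_experiment

__all__ = ["run_pipeline"]

log = logging.getLogger("phagedrop")

_STAGES = ("simulate", "render", "analyze-images", "analyze-growth")


def _build_sim_params(config: ExperimentConfig) -> SimParams:
    return SimParams(**config.sim)


def _build_optics(config: ExperimentConfig) -> OpticsParams:
    optics = dict(config.optics)
    if "shading" in optics:
        optics["shading"] = ShadingFieldSpec(**optics["shading"])
    if "droplet_centers_um" in optics:
        optics["droplet_centers_um"] = tuple(
            tuple(c) for c in optics["droplet_centers_um"]
        )
    if "image_size_px" in optics:
        optics["image_size_px"] = tuple(optics["image_size_px"])
    return OpticsParams(**optics)


def _config_hash(config: ExperimentConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: ExperimentConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages in order and write a manifest.

    Input paths are validated before any output is produced; any stage
    error aborts with a stage-tagged message.  Returns the manifest dict.
    """
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {list(_STAGES)}")
    if seed is None:
        seed = config.seed
    out_dir = Path(out_dir)

    # validate declared inputs before writing anything
    if "analyze-images" in config.stages and "render" not in config.stages:
        for name in ("stack_path", "flatfield_path", "rois_path"):
            value = getattr(config, name)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(f"[analyze-images] missing input {name}: {value}")
    if ("analyze-growth" in config.stages
            and "simulate" not in config.stages
            and "analyze-images" not in config.stages):
        if config.trajectories_path is None or not Path(config.trajectories_path).exists():
            raise FileNotFoundError(
                f"[analyze-growth] missing input trajectories: {config.trajectories_path}"
            )

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    timings: dict[str, float] = {}
    phage = PHAGE_PRESETS[config.phage] if config.phage else None
    trajectories = None
    stack = corrector = rois = None

    for stage in config.stages:
        t_start = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            if stage == "simulate":
                params = _build_sim_params(config)
                trajectories = simulate_experiment(params, phage, config.n_droplets, rng=seed)
                path = out_dir / "trajectories.csv"
                write_trajectory_csv(trajectories, path)
                outputs.append(path.name)
            elif stage == "render":
                params = _build_sim_params(config)
                optics = _build_optics(config)
                rng = np.random.default_rng(seed)
                if trajectories is None:
                    trajectories = simulate_experiment(
                        params, phage, len(optics.droplet_centers_um), rng=seed
                    )
                counts = np.column_stack(
                    [
                        np.round(t.values / max(params.signal_per_cell, 1e-300)).astype(int)
                        for t in trajectories[: len(optics.droplet_centers_um)]
                    ]
                )
                stack = render_stack(
                    counts, optics, dt_min=params.dt_min,
                    t0_min=params.dead_time_min, rng=rng,
                )
                flat = render_flatfield(optics, rng=rng)
                rois = droplet_rois(optics)
                save_stack(stack, out_dir / "stack.tif", dtype="float32")
                save_stack(flat, out_dir / "flatfield.tif", dtype="float32")
                write_rois_csv(rois, out_dir / "rois.csv")
                corrector = build_shading_corrector(flat)
                outputs += ["stack.tif", "flatfield.tif", "rois.csv"]
            elif stage == "analyze-images":
                if stack is None:
                    stack = load_stack(config.stack_path)
                    corrector = build_shading_corrector(load_stack(config.flatfield_path))
                    rois = read_rois_csv(config.rois_path)
                trajectories = extract_trajectories(
                    stack, corrector, rois, strategy=config.mask_strategy
                )
                path = out_dir / "trajectories.csv"
                write_trajectory_csv(trajectories, path)
                outputs.append(path.name)
            elif stage == "analyze-growth":
                if trajectories is None:
                    trajectories = read_trajectory_csv(config.trajectories_path)
                table, summary = cohort_summary(
                    trajectories, preset=config.preset, window_min=config.window_min
                )
                table.to_csv(out_dir / "results.csv", index=False)
                (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
                outputs += ["results.csv", "summary.json"]
        except Exception as err:
            raise RuntimeError(f"[{stage}] {err}") from err
        timings[stage] = time.perf_counter() - t_start
        log.info("stage %s: done in %.2f s", stage, timings[stage])

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": _config_hash(config),
        "stages": list(config.stages),
        "outputs": sorted(set(outputs)),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
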