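"""End-to-end orchestration: register -> detect/link -> metrics -> tables."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frame_io, metrics as metrics_mod, registration, tracking
from .config import RunConfig
from .errors import PhenotrackError
from .frame_io import FrameStack

log = logging.getLogger("phenotrack")


@dataclass
class PipelineResult:
    registration: registration.RegistrationResult
    detections: list[tracking.CellDetection]
    trajectories: list[tracking.Trajectory]
    metrics: list[metrics_mod.MigrationMetrics]
    summary: metrics_mod.CohortSummary | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def track_stack(
    registered: np.ndarray,
    channel_roles: dict[str, int],
    cfg: RunConfig,
) -> tuple[list[tracking.CellDetection], list[tracking.Trajectory]]:
    """Detect nuclei in every registered frame and link them."""
    det_params = cfg.detection_params()
    thresholds = cfg.phase_thresholds()
    dyn = float(registered[:, [channel_roles["red"], channel_roles["green"]]].max())
    floor = cfg["phase"]["intensity_floor_frac"] * dyn
    detections: list[tracking.CellDetection] = []
    for t in range(registered.shape[0]):
        detections.extend(
            tracking.detect_cells(
                registered[t, channel_roles["red"]],
                registered[t, channel_roles["green"]],
                t=t,
                params=det_params,
                thresholds=thresholds,
                intensity_floor=floor,
            )
        )
    trajectories = tracking.link_tracks(detections, cfg.link_params())
    return detections, trajectories


def run_pipeline(stack: FrameStack, cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full analysis on an in-memory stack."""
    cfg = cfg or RunConfig()
    cfg.validate()
    t0 = time.time()
    log.info("registering %d frames ...", stack.n_frames)
    seg = dict(cfg["segmentation"])
    seg_kwargs = dict(
        smoothing_sigma=seg["smoothing_sigma"],
        threshold_method=seg["threshold_method"],
        fixed_threshold=seg["fixed_threshold"],
        min_area_px=seg["min_area_px"],
    )
    reg = registration.register_stack(
        stack,
        params=cfg.registration_params(),
        gray_recipe=cfg["gray_recipe"],
        seg_kwargs=seg_kwargs,
    )
    log.info("registration done in %.1f s", time.time() - t0)

    registered = registration.registered_stack_frames(stack, reg)
    detections, trajectories = track_stack(registered, dict(stack.channel_roles), cfg)
    log.info("%d detections, %d trajectories", len(detections), len(trajectories))

    cell_metrics = metrics_mod.compute_metrics(trajectories, stack.pixel_size_um)
    summary = (
        metrics_mod.rank_and_ratio(cell_metrics, cfg["ranking"]["top_n"])
        if cell_metrics
        else None
    )
    tables = {
        "transforms": registration.transforms_table(reg),
        "detections": tracking.detections_table(detections),
        "trajectories": tracking.trajectories_table(trajectories),
        "metrics": metrics_mod.metrics_table(cell_metrics),
    }
    if summary is not None:
        tables["summary"] = metrics_mod.summary_table(summary)
    return PipelineResult(
        registration=reg,
        detections=detections,
        trajectories=trajectories,
        metrics=cell_metrics,
        summary=summary,
        tables=tables,
    )


def run_from_config(cfg: RunConfig) -> PipelineResult:
    """Load the configured input, run, and write all outputs."""
    cfg.validate()
    if not cfg["input"]:
        raise PhenotrackError("config has no input path")
    stack = frame_io.load_stack(
        cfg["input"], cfg["channel_map"], cfg["calibration"]
    )
    result = run_pipeline(stack, cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    frame_io.write_tables(result.tables, out)
    cfg.write(out / "effective_config.yaml")
    if cfg["plots"]:
        from . import plots

        plots.trajectory_map(result.trajectories, out / "trajectory_map.png")
        plots.vector_map(result.trajectories, out / "vector_map.png")
        plots.hue_curves(result.trajectories, out / "hue_curves.png")
    return result
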