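"""End-to-end orchestration of the analysis stages on one scene directory.

Stages: simulate -> register -> segment -> quantify -> features -> demux ->
track-lumen -> track-cells -> align -> morphotypes -> motion.  Each stage
persists its outputs under the run directory together with a marker file
holding the configuration hash; a rerun with the same configuration skips
completed stages, and deleting a stage's outputs recomputes that stage and
everything downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import morpho, motion, register, shapes, synthgen, tissue, tracking
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "register",
    "segment",
    "quantify",
    "features",
    "demux",
    "track_lumen",
    "track_cells",
    "align",
    "morphotypes",
    "motion",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, fingerprint: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {exc}")
        self.stage = stage


def scene_params_from_config(config: PipelineConfig) -> synthgen.SceneParams:
    kwargs = dict(config.scene)
    specs = kwargs.pop("lumen_specs", None)
    if specs is not None:
        kwargs["lumen_specs"] = [
            s if isinstance(s, synthgen.LumenSpec)
            else synthgen.LumenSpec(
                birth_frame=s["birth_frame"],
                centre=tuple(s["centre"]),
                radius_schedule=tuple(s["radius_schedule"]),
            )
            for s in specs
        ]
    for key in ("grid_shape", "spacing", "drift_per_frame",
                "organoid_radius_schedule"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    geom = kwargs.get("class_geometry")
    if geom is not None:
        kwargs["class_geometry"] = {
            cls: g if isinstance(g, synthgen.ClassGeometry)
            else synthgen.ClassGeometry(**g)
            for cls, g in geom.items()
        }
    elong = kwargs.get("elongation_by_class")
    if elong is not None:
        kwargs["elongation_by_class"] = {
            cls: tuple(v) for cls, v in elong.items()
        }
    kwargs.setdefault("seed", config.seed)
    return synthgen.SceneParams(**kwargs)


class PipelineRun:
    """File layout + caching for one pipeline run directory."""

    def __init__(self, config: PipelineConfig, out_dir):
        config.validate()
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.hash = config.hash()

    def dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def marker(self, stage: str) -> Path:
        return self.out / stage / ".complete.json"

    def is_cached(self, stage: str) -> bool:
        m = self.marker(stage)
        if not m.exists():
            return False
        try:
            return json.loads(m.read_text())["config_hash"] == self.hash
        except Exception:
            return False

    def mark(self, stage: str, **info) -> None:
        self.marker(stage).write_text(
            json.dumps({"config_hash": self.hash, "stage": stage, **info})
        )

    def npz(self, stage: str) -> Path:
        return self.dir(stage) / "arrays.npz"


def _write_csv(path: Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# stages (each loads its inputs from disk so runs are resumable)


def stage_simulate(run: PipelineRun) -> None:
    params = scene_params_from_config(run.config)
    scene = synthgen.generate_scene(params)
    d = run.dir("simulate")
    np.savez_compressed(
        run.npz("simulate"),
        gfp=scene.timelapse["gfp"],
        rfp=scene.timelapse["rfp"],
        semantic=scene.gt_semantic,
        lumen_instances=scene.gt_lumen_instances,
        cell_instances=scene.gt_cell_instances,
        offsets=scene.gt_offsets,
    )
    _write_csv(d / "gt_cells.csv", scene.gt_cells)
    _write_csv(
        d / "gt_fusions.csv",
        pd.DataFrame(scene.gt_fusions,
                     columns=["frame", "surviving", "absorbed"]),
    )
    meta = {
        "spacing": list(params.spacing),
        "frame_interval": params.frame_interval,
        "n_frames": params.n_frames,
        "labels": {str(k): v for k, v in scene.gt_labels.items()},
    }
    (d / "scene.json").write_text(json.dumps(meta))


def _load_scene(run: PipelineRun):
    d = run.dir("simulate")
    arrays = np.load(run.npz("simulate"))
    meta = json.loads((d / "scene.json").read_text())
    return arrays, meta


def stage_register(run: PipelineRun) -> None:
    arrays, meta = _load_scene(run)
    frames = list(arrays[run.config.register_channel])
    offsets = register.sequence_offsets(frames, window=run.config.register_window)
    timelapse = {"gfp": arrays["gfp"], "rfp": arrays["rfp"]}
    masks = {
        k: arrays[k] for k in ("semantic", "lumen_instances", "cell_instances")
    }
    reg, reg_masks = register.apply_offsets(timelapse, offsets, masks)
    d = run.dir("register")
    np.savez_compressed(run.npz("register"), **reg, **reg_masks)
    _write_csv(
        d / "offsets.csv",
        pd.DataFrame(offsets.offsets, columns=["dz", "dy", "dx"]).assign(
            frame=range(offsets.n_frames)
        ),
    )


def stage_segment(run: PipelineRun) -> None:
    cfg = run.config
    arrays, meta = _load_scene(run)
    reg = np.load(run.npz("register"))
    spacing = meta["spacing"]
    summed = tissue.summed_channels({"gfp": reg["gfp"], "rfp": reg["rfp"]})
    boxes = tissue.annotations_from_ground_truth(
        reg["semantic"],
        n_boxes_per_class=cfg.annotation_boxes_per_class,
        seed=cfg.seed,
    )
    clf = tissue.train_tissue_rf(
        summed,
        boxes,
        n_estimators=cfg.rf_trees,
        max_depth=cfg.rf_depth,
        max_samples=cfg.rf_max_samples,
        sigma_min=cfg.sigma_min,
        sigma_max=cfg.sigma_max,
        seed=cfg.seed,
    )
    semantic = np.stack(
        [
            tissue.postprocess_semantic(
                tissue.predict_semantic(summed[t], clf),
                spacing,
                smooth_sigma_um=cfg.smooth_sigma_um,
            )
            for t in range(summed.shape[0])
        ]
    )
    lumen_instances = tissue.postprocess_lumen_timeseries(
        semantic,
        spacing,
        opening_iterations=cfg.lumen_opening_iterations,
        min_volume_um3=cfg.lumen_min_volume_um3,
    )
    np.savez_compressed(
        run.npz("segment"), semantic=semantic, lumen_instances=lumen_instances
    )
    (run.dir("segment") / "holdout.json").write_text(
        json.dumps(clf.holdout_accuracy)
    )


def stage_quantify(run: PipelineRun) -> None:
    _, meta = _load_scene(run)
    seg = np.load(run.npz("segment"))
    metrics = tissue.quantify_tissue(
        seg["semantic"], seg["lumen_instances"], meta["spacing"]
    )
    _write_csv(run.dir("quantify") / "tissue_metrics.csv", metrics)


def stage_features(run: PipelineRun) -> None:
    cfg = run.config
    arrays, meta = _load_scene(run)
    reg = np.load(run.npz("register"))
    labels = {int(k): v for k, v in meta["labels"].items()}
    spacing = meta["spacing"]
    tables = []
    id_channel = {
        sid: synthgen.CLASS_CHANNEL.get(lbl, "gfp")
        for sid, lbl in labels.items()
    }
    for t in range(meta["n_frames"]):
        inst = reg["cell_instances"][t]
        for ch in ("gfp", "rfp"):
            ids = [sid for sid, c in id_channel.items() if c == ch]
            sel = np.where(np.isin(inst, ids), inst, 0)
            tab = morpho.extract_features(
                sel, reg[ch][t], spacing, channel=ch, frame=t,
                iso_voxel_um=cfg.iso_voxel_um,
            )
            if len(tab):
                tab["label"] = tab["structure_id"].map(labels)
                tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    table = morpho.qc_filter(
        table,
        min_volume_voxels=cfg.qc_min_volume_voxels,
        min_max_intensity=cfg.qc_min_max_intensity,
    )
    _write_csv(run.dir("features") / "features.csv", table)


def stage_demux(run: PipelineRun) -> None:
    cfg = run.config
    table = pd.read_csv(run.dir("features") / "features.csv")
    model = morpho.train_demux(
        table,
        test_fraction=cfg.demux_test_fraction,
        seed=cfg.seed,
        grid=cfg.demux_grid,
    )
    pred = morpho.demux_predict(model, table)
    d = run.dir("demux")
    _write_csv(d / "demultiplexed.csv", pred)
    _write_csv(d / "grid_search.csv", model.grid_results)
    (d / "summary.json").write_text(
        json.dumps(
            {"test_accuracy": model.test_accuracy,
             "best_params": {k: (v if v is None else int(v))
                             for k, v in model.best_params.items()}}
        )
    )


def stage_track_lumen(run: PipelineRun) -> None:
    cfg = run.config
    _, meta = _load_scene(run)
    seg = np.load(run.npz("segment"))
    params = tracking.lumen_params(
        max_dist_um=cfg.lumen_max_dist_um,
        min_vol_um3=cfg.lumen_node_min_vol_um3,
        appear_cost=cfg.appear_cost,
        disappear_cost=cfg.disappear_cost,
    )
    cg = tracking.build_graph(seg["lumen_instances"], meta["spacing"], params)
    sol = tracking.solve(cg)
    fusion_table, counts, _ = tracking.extract_fusions(
        sol, meta["frame_interval"]
    )
    d = run.dir("track_lumen")
    _write_csv(d / "fusions.csv", fusion_table)
    _write_csv(d / "fusion_counts.csv", counts)
    _write_csv(
        d / "tracks.csv",
        tracking.solution_to_tracks(sol, cg, meta["frame_interval"]),
    )


def stage_track_cells(run: PipelineRun) -> None:
    cfg = run.config
    _, meta = _load_scene(run)
    reg = np.load(run.npz("register"))
    params = tracking.cell_params(
        max_dist_um=cfg.cell_max_dist_um,
        min_mask_vol_um3=cfg.cell_mask_min_vol_um3,
        min_vol_um3=cfg.cell_node_min_vol_um3,
        appear_cost=cfg.appear_cost,
        disappear_cost=cfg.disappear_cost,
    )
    cg = tracking.build_graph(reg["cell_instances"], meta["spacing"], params)
    sol = tracking.solve(cg)
    _write_csv(
        run.dir("track_cells") / "tracks.csv",
        tracking.solution_to_tracks(sol, cg, meta["frame_interval"]),
    )


def stage_align(run: PipelineRun) -> None:
    cfg = run.config
    _, meta = _load_scene(run)
    reg = np.load(run.npz("register"))
    seg = np.load(run.npz("segment"))
    tables = []
    for t in range(meta["n_frames"]):
        organoid = seg["semantic"][t] != tissue.BACKGROUND
        inst = reg["cell_instances"][t]
        if not np.any(inst) or not np.any(organoid):
            continue
        tab = shapes.cell_alignment_table(
            inst, organoid, meta["spacing"],
            mesh_step=cfg.mesh_step, cell_step=cfg.cell_mesh_step,
        )
        tab["frame"] = t
        tables.append(tab)
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    _write_csv(run.dir("align") / "alignment.csv", out)


def stage_morphotypes(run: PipelineRun) -> None:
    cfg = run.config
    _, meta = _load_scene(run)
    pred = pd.read_csv(run.dir("demux") / "demultiplexed.csv")
    pred = pred[pred["predicted_label"] != morpho.FAULTY].reset_index(drop=True)
    n_pcs = min(cfg.n_pcs, max(2, len(pred) - 2))
    assignment = shapes.cluster_morphotypes(
        pred,
        n_pcs=n_pcs,
        resolution=cfg.leiden_resolution,
        seed=cfg.seed,
        paga_threshold=cfg.paga_threshold,
    )
    table = assignment.table.copy()
    table["condition"] = "synthetic"
    table["day"] = (
        table["frame"] * meta["frame_interval"] / 24.0
    ).astype(int)
    d = run.dir("morphotypes")
    _write_csv(d / "assignments.csv", table)
    props = shapes.cluster_proportions(table)
    props.reset_index().to_csv(d / "proportions.csv", index=False)
    _write_csv(
        d / "shannon.csv",
        shapes.bootstrap_shannon(table, B=cfg.bootstrap_B, seed=cfg.seed),
    )
    (d / "cluster_graph.json").write_text(
        json.dumps(
            {
                "nodes": sorted(assignment.cluster_graph.nodes),
                "edges": [
                    [int(u), int(v), float(w["weight"])]
                    for u, v, w in assignment.cluster_graph.edges(data=True)
                ],
            }
        )
    )


def stage_motion(run: PipelineRun) -> None:
    cfg = run.config
    _, meta = _load_scene(run)
    seg = np.load(run.npz("segment"))
    tracks = pd.read_csv(run.dir("track_cells") / "tracks.csv")
    com = motion.organoid_center_of_mass(
        seg["semantic"] != tissue.BACKGROUND, meta["spacing"]
    )
    d = run.dir("motion")
    _write_csv(
        d / "radial_coordination.csv",
        motion.radial_coordination(
            tracks, com, meta["frame_interval"],
            lookback_hours=cfg.motion_lookback_hours,
        ),
    )
    _write_csv(
        d / "velocities.csv",
        motion.smoothed_velocities(
            tracks, meta["frame_interval"], window=cfg.velocity_window
        ),
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "register": stage_register,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "features": stage_features,
    "demux": stage_demux,
    "track_lumen": stage_track_lumen,
    "track_cells": stage_track_cells,
    "align": stage_align,
    "morphotypes": stage_morphotypes,
    "motion": stage_motion,
}


def run_pipeline(config: PipelineConfig, out_dir,
                 stages=STAGES) -> dict[str, float]:
    """Execute the pipeline; returns per-stage wall-clock timings (cached
    stages report 0).  A stage error aborts with the stage name and the
    configuration hash as the input fingerprint."""
    run = PipelineRun(config, out_dir)
    timings: dict[str, float] = {}
    upstream_ran = False
    for stage in stages:
        if run.is_cached(stage) and not upstream_ran:
            logger.info("stage %s cached, skipping", stage)
            timings[stage] = 0.0
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise StageError(stage, run.hash, exc) from exc
        dt = time.perf_counter() - t0
        run.mark(stage, seconds=dt)
        timings[stage] = dt
        upstream_ran = True
        logger.info("stage %s finished in %.1fs", stage, dt)
    (run.out / "run.json").write_text(
        json.dumps({"config_hash": run.hash, "timings": timings,
                    "config": dataclasses.asdict(config)}, default=str)
    )
    return timings
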