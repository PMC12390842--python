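"""Shared synthetic-scene fixtures (session-scoped: scenes are reused)."""

from __future__ import annotations

import numpy as np
import pytest

from organomorph import morpho, shapes, synthgen, tissue


@pytest.fixture(scope="session")
def fusion_scene():
    """Four lumens, three scheduled fusions (frames 3, 6, 9)."""
    return synthgen.generate_scene(synthgen.three_fusion_scene_params(seed=2))


@pytest.fixture(scope="session")
def drift_scene():
    """Static organoid drifting by (1, 2, 3) voxels per frame, 10 frames."""
    return synthgen.generate_scene(synthgen.drift_scene_params(seed=1))


@pytest.fixture(scope="session")
def demux_scene():
    """Five label classes plus faulty debris across two channels, 4 frames."""
    return synthgen.generate_scene(synthgen.demux_scene_params(seed=3))


@pytest.fixture(scope="session")
def qc_features(demux_scene):
    table = morpho.extract_scene_features(demux_scene)
    return morpho.qc_filter(table)


@pytest.fixture(scope="session")
def demux_model(qc_features):
    return morpho.train_demux(qc_features, seed=0)


@pytest.fixture(scope="session")
def radial_alignment_table():
    scene = synthgen.generate_scene(
        synthgen.alignment_scene_params(seed=5, radial_fraction=1.0)
    )
    return scene, shapes.cell_alignment_table(
        scene.gt_cell_instances[0],
        scene.gt_semantic[0] != 0,
        scene.spacing,
    )


@pytest.fixture(scope="session")
def tangential_alignment_table():
    scene = synthgen.generate_scene(
        synthgen.alignment_scene_params(
            seed=6, radial_fraction=0.0, nonradial_orientation="tangential"
        )
    )
    return scene, shapes.cell_alignment_table(
        scene.gt_cell_instances[0],
        scene.gt_semantic[0] != 0,
        scene.spacing,
    )


@pytest.fixture(scope="session")
def tissue_scene():
    return synthgen.generate_scene(
        synthgen.tissue_scene_params(seed=4, n_frames=2)
    )


@pytest.fixture(scope="session")
def tissue_segmentation(tissue_scene):
    """Trained pixel classifier plus post-processed prediction of frame 0."""
    scene = tissue_scene
    summed = tissue.summed_channels(scene.timelapse)
    boxes = tissue.annotations_from_ground_truth(
        scene.gt_semantic, n_boxes_per_class=8, seed=0
    )
    clf = tissue.train_tissue_rf(summed, boxes, seed=0)
    raw = tissue.predict_semantic(summed[0], clf)
    post = tissue.postprocess_semantic(raw, scene.spacing)
    return scene, clf, raw, post


@pytest.fixture(scope="session")
def tracking_scene():
    return synthgen.generate_scene(synthgen.tracking_scene_params(seed=7))


def ball_volume(shape, spacing, centre, radius):
    return synthgen._ball_mask(shape, spacing, np.asarray(centre, float),
                               radius)
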