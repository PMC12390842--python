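"""Pipeline configuration with documented defaults and provenance hashing.

Stage parameters default to the reference analysis values (20,000 um^3
minimum lumen volume; 1,110 um lumen / 24.3 um cell linking distances;
appear/disappear costs 0.8; 1,444 um^3 cell mask filter and 481.6 um^3 cell
node reference volume; registration window 3; Leiden resolutions 0.6 / 1.5
with 5 / 4 principal components; 1,000 bootstrap resamples).  Every output
carries the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # synthetic scene (kwargs for synthgen.SceneParams; seed injected)
    scene: dict = field(default_factory=dict)
    # registration
    register_channel: str = "gfp"
    register_window: int = 3
    # tissue segmentation
    sigma_min: float = 1.0
    sigma_max: float = 64.0
    rf_trees: int = 50
    rf_depth: int = 25
    rf_max_samples: float = 0.05
    annotation_boxes_per_class: int = 8
    smooth_sigma_um: float = 2.776
    lumen_min_volume_um3: float = 20_000.0
    lumen_opening_iterations: int = 4
    # morphometrics / demux
    iso_voxel_um: float = 0.694
    qc_min_volume_voxels: int = 100
    qc_min_max_intensity: float = 20.0
    demux_test_fraction: float = 0.1
    demux_grid: dict = field(
        default_factory=lambda: {
            "n_estimators": [50, 100, 200],
            "max_depth": [5, 10, 20, None],
        }
    )
    # tracking
    lumen_max_dist_um: float = 1110.0
    lumen_node_min_vol_um3: float = 20_000.0
    appear_cost: float = 0.8
    disappear_cost: float = 0.8
    cell_max_dist_um: float = 24.3
    cell_mask_min_vol_um3: float = 1_444.0
    cell_node_min_vol_um3: float = 481.6
    # shapes / morphotypes
    mesh_step: int = 4
    cell_mesh_step: int = 2
    leiden_resolution: float = 0.6
    n_pcs: int = 5
    paga_threshold: float = 0.1
    bootstrap_B: int = 1000
    # motion
    motion_lookback_hours: float = 24.0
    velocity_window: int = 10

    def validate(self) -> None:
        checks = [
            self.register_window >= 2,
            self.sigma_min > 0 and self.sigma_max >= self.sigma_min,
            self.iso_voxel_um > 0,
            0 < self.demux_test_fraction < 1,
            self.lumen_min_volume_um3 >= 0,
            self.appear_cost >= 0 and self.disappear_cost >= 0,
            self.n_pcs >= 1,
            self.bootstrap_B >= 1,
        ]
        if not all(checks):
            raise ValueError("configuration parameter out of documented range")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(o) for o in obj]
            if isinstance(obj, list):
                return [listify(o) for o in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(
            yaml.safe_dump(listify(dataclasses.asdict(self)),
                           sort_keys=True)
        )


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration for the bundled end-to-end demonstration.

    Scene and thresholds are scaled to a small synthetic organoid so the
    whole pipeline runs in minutes; reference-analysis values stay the
    defaults everywhere the scene scale permits.
    """
    return PipelineConfig(
        seed=seed,
        scene={
            "grid_shape": (40, 104, 104),
            "spacing": (2.0, 1.0, 1.0),
            "n_frames": 4,
            "organoid_radius_schedule": (36.0, 36.5, 37.0, 37.5),
            "lumen_specs": [
                {
                    "birth_frame": 0,
                    "centre": (40.0, 52.0, 52.0),
                    "radius_schedule": (10.0, 10.5, 11.0, 11.5),
                }
            ],
            "n_cells_per_class": {
                "histone": 5, "lamin": 5, "actin": 5,
                "tubulin": 4, "membrane": 4,
            },
            "n_faulty": 5,
            # elongated classes scaled to the small demo organoid
            "class_geometry": {
                "histone": {"major_mean": 3.8, "major_sd": 0.4},
                "lamin": {"major_mean": 5.0, "major_sd": 0.5},
                "actin": {"major_mean": 7.5, "major_sd": 0.5},
                "tubulin": {"major_mean": 8.5, "major_sd": 0.5},
                "membrane": {"major_mean": 7.0, "major_sd": 0.5},
            },
            "cell_jitter_um": 0.3,
            "drift_per_frame": (0, 1, 1),
            "noise_sd": 3.0,
        },
        lumen_min_volume_um3=2_000.0,
        lumen_node_min_vol_um3=2_000.0,
        cell_mask_min_vol_um3=80.0,
        cell_node_min_vol_um3=100.0,
        demux_grid={"n_estimators": [50], "max_depth": [10]},
        bootstrap_B=200,
    )
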