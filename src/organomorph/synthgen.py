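"""Synthetic 4D organoid scene generator with full ground truth.

Generates dual-channel (GFP/RFP) time-lapse volumes of a growing organoid
containing expanding and fusing lumens and sparsely labelled cells from five
morphological label classes (histone, lamin, actin, tubulin, membrane)
multiplexed into the two channels, plus optional "faulty" debris blobs.
Every stage of the analysis pipeline (registration, tissue segmentation,
morphometry/demultiplexing, alignment statistics, tracking, motion) can be
validated against the returned ground truth.

Conventions: arrays are indexed ``(z, y, x)``, 0-based; physical position =
index * spacing; all distances in micrometres (um), time in hours.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

CLASSES = ("histone", "lamin", "actin", "tubulin", "membrane")
FAULTY = "faulty"
#: fixed channel multiplexing of the label classes
CLASS_CHANNEL = {
    "histone": "gfp",
    "actin": "gfp",
    "lamin": "rfp",
    "membrane": "rfp",
    "tubulin": "rfp",
}
CHANNELS = ("gfp", "rfp")
#: classes rendered as hollow shells (nuclear envelope / plasma membrane)
SHELL_CLASSES = frozenset({"lamin", "membrane"})
#: classes whose major axis carries orientation information
ELONGATED_CLASSES = frozenset({"actin", "tubulin"})


class PlacementError(RuntimeError):
    """Raised when a label class cannot be placed without overlap."""


class FusionGeometryError(RuntimeError):
    """Raised when scheduled lumen fusion partners are not adjacent."""


@dataclass
class ClassGeometry:
    """Size prior of one label class: semi-major axis ~ N(mean, sd) um."""

    major_mean: float
    major_sd: float


#: default class-conditional size priors (semi-major axis, um)
DEFAULT_GEOMETRY: dict[str, ClassGeometry] = {
    "histone": ClassGeometry(3.8, 0.4),
    "lamin": ClassGeometry(5.0, 0.5),
    "actin": ClassGeometry(9.0, 1.0),
    "tubulin": ClassGeometry(11.0, 1.2),
    "membrane": ClassGeometry(8.0, 0.8),
}

#: default class-conditional axis-ratio (minor/major) priors: (mean, sd)
DEFAULT_ELONGATION: dict[str, tuple[float, float]] = {
    "histone": (0.85, 0.05),
    "lamin": (0.80, 0.05),
    "actin": (0.32, 0.05),
    "tubulin": (0.22, 0.04),
    "membrane": (0.65, 0.07),
}


@dataclass
class LumenSpec:
    """One lumen: birth frame, centre (z,y,x um) and per-frame radius (um)."""

    birth_frame: int
    centre: tuple[float, float, float]
    radius_schedule: tuple[float, ...]


@dataclass
class SceneParams:
    grid_shape: tuple[int, int, int] = (48, 104, 104)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    n_frames: int = 6
    frame_interval: float = 1.0  # hours
    organoid_radius_schedule: tuple[float, ...] | None = None
    lumen_specs: list[LumenSpec] = field(default_factory=list)
    fusion_schedule: list[tuple[int, int, int]] = field(default_factory=list)
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CLASSES}
    )
    n_faulty: int = 0
    radial_fraction: float = 0.0
    nonradial_orientation: str = "random"  # "random" | "tangential"
    elongation_by_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELONGATION)
    )
    class_geometry: dict[str, ClassGeometry] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    drift_per_frame: tuple[int, int, int] = (0, 0, 0)
    cell_jitter_um: float = 0.0
    tissue_intensity: float = 40.0
    lumen_intensity: float = 5.0
    cell_intensity: tuple[float, float] = (160.0, 15.0)  # mean, sd
    noise_sd: float = 3.0
    shell_wall_um: float | None = None  # default: 2 voxels at finest spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organoid_radius_schedule is None:
            # default: modest growth filling ~80% of the shortest half-extent
            # (scenes for specific analyses pass explicit schedules)
            extent = min(
                n * s for n, s in zip(self.grid_shape, self.spacing)
            )
            r0, r1 = 0.55 * extent / 2, 0.8 * extent / 2
            self.organoid_radius_schedule = tuple(
                np.linspace(r0, r1, self.n_frames)
            )
        self.validate()

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.radial_fraction <= 1.0:
            raise ValueError("radial_fraction must be in [0, 1]")
        if self.nonradial_orientation not in ("random", "tangential"):
            raise ValueError("nonradial_orientation must be random|tangential")
        if len(self.organoid_radius_schedule) != self.n_frames:
            raise ValueError("organoid_radius_schedule length != n_frames")
        for spec in self.lumen_specs:
            if len(spec.radius_schedule) != self.n_frames:
                raise ValueError("lumen radius_schedule length != n_frames")
        n_lumens = len(self.lumen_specs)
        for frame, a, b in self.fusion_schedule:
            for lid in (a, b):
                if not 1 <= lid <= n_lumens:
                    raise ValueError(
                        f"fusion_schedule references unknown lumen id {lid}"
                    )
            if not 0 <= frame < self.n_frames:
                raise ValueError("fusion frame outside movie")
        for cls in self.n_cells_per_class:
            if cls not in CLASSES:
                raise ValueError(f"unknown label class {cls!r}")

    @property
    def wall_um(self) -> float:
        if self.shell_wall_um is not None:
            return self.shell_wall_um
        return 2.0 * min(self.spacing)

    @property
    def centre_um(self) -> np.ndarray:
        return np.array(
            [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)]
        )


@dataclass
class SyntheticScene:
    """A generated scene plus its complete ground truth.

    ``timelapse`` maps channel name -> float32 array (t, z, y, x); masks are
    one array per frame stacked on axis 0.  All masks/intensities are given
    in *observed* (drifted) coordinates; ``gt_offsets`` holds the cumulative
    integer drift applied to frame t so downstream registration can be
    validated exactly.
    """

    params: SceneParams
    timelapse: dict[str, np.ndarray]
    gt_semantic: np.ndarray  # (t,z,y,x) uint8: 0 bg, 1 lumen, 2 tissue
    gt_lumen_instances: np.ndarray  # (t,z,y,x) uint16
    gt_cell_instances: np.ndarray  # (t,z,y,x) uint16
    gt_labels: dict[int, str]  # cell structure_id -> class
    gt_cells: pd.DataFrame  # structure_id, frame, class, channel, centroids
    gt_tracks: pd.DataFrame  # alias view: track_id == structure_id
    gt_fusions: list[tuple[int, int, int]]  # (frame, surviving, absorbed)
    gt_offsets: np.ndarray  # (t, 3) cumulative integer drift
    gt_orientations: dict[int, np.ndarray]  # structure_id -> unit major axis

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.params.spacing

    def lumen_count_series(self) -> np.ndarray:
        """Ground-truth lumen count per frame (births - realized fusions)."""
        counts = np.zeros(self.params.n_frames, dtype=int)
        for t in range(self.params.n_frames):
            born = sum(
                1 for s in self.params.lumen_specs if s.birth_frame <= t
            )
            fused = sum(1 for f, _, _ in self.gt_fusions if f <= t)
            counts[t] = born - fused
        return counts


# ---------------------------------------------------------------------------
# rasterization helpers


def _ball_mask(shape, spacing, centre_um, radius_um):
    """Boolean mask of a physical ball on an anisotropic grid."""
    zz = np.arange(shape[0]) * spacing[0] - centre_um[0]
    yy = np.arange(shape[1]) * spacing[1] - centre_um[1]
    xx = np.arange(shape[2]) * spacing[2] - centre_um[2]
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    return d2 <= radius_um**2


def _orthonormal_basis(major: np.ndarray, rng: np.random.Generator):
    """Orthonormal frame whose first row is the given unit vector."""
    major = major / np.linalg.norm(major)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(major @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    b = np.cross(major, helper)
    b /= np.linalg.norm(b)
    c = np.cross(major, b)
    return np.stack([major, b, c])


def _rasterize_ellipsoid(
    out: np.ndarray,
    spacing,
    centre_um,
    axes_um,
    basis,
    value,
    hollow_wall_um: float | None = None,
):
    """Paint an (optionally hollow) ellipsoid instance label into ``out``.

    Returns the number of voxels painted.
    """
    spacing = np.asarray(spacing, float)
    r_bound = float(np.max(axes_um))
    lo = np.maximum(
        0, np.floor((np.asarray(centre_um) - r_bound) / spacing).astype(int)
    )
    hi = np.minimum(
        np.array(out.shape),
        np.ceil((np.asarray(centre_um) + r_bound) / spacing).astype(int) + 1,
    )
    if np.any(lo >= hi):
        return 0
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * spacing[a] - centre_um[a] for a in range(3)],
        indexing="ij",
    )
    pts = np.stack(grids, axis=-1)  # local physical offsets
    proj = pts @ basis.T  # coords in ellipsoid frame
    q = np.sum((proj / np.asarray(axes_um)) ** 2, axis=-1)
    inside = q <= 1.0
    if hollow_wall_um is not None:
        inner = np.maximum(np.asarray(axes_um) - hollow_wall_um, 0.4)
        q_in = np.sum((proj / inner) ** 2, axis=-1)
        inside &= q_in > 1.0
    sub = out[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    sub[inside] = value
    return int(inside.sum())


def integer_shift(volume: np.ndarray, offset) -> np.ndarray:
    """Shift a 3D array by an integer (dz,dy,dx), zero-filling vacated voxels."""
    out = np.zeros_like(volume)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        d = int(d)
        n = volume.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    out[tuple(dst)] = volume[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# cell placement


@dataclass
class _Cell:
    structure_id: int
    label: str
    channel: str
    centre: np.ndarray  # physical um, frame-0 coordinates
    axes: np.ndarray  # semi-axes (major, minor, minor) um
    basis: np.ndarray  # 3x3 orthonormal, rows: major/minor/minor directions
    brightness: float
    hollow: bool
    pieces: list | None = None  # for faulty debris: (offset, radius) list

    @property
    def bound_radius(self) -> float:
        return float(np.max(self.axes))


def _sample_orientation(
    params: SceneParams, centre: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Major-axis direction for an elongated cell."""
    radial = centre - params.centre_um
    nrm = np.linalg.norm(radial)
    radial = radial / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    if rng.random() < params.radial_fraction:
        return radial
    if params.nonradial_orientation == "tangential":
        v = rng.standard_normal(3)
        v -= (v @ radial) * radial
        n = np.linalg.norm(v)
        if n < 1e-9:
            return _sample_orientation(params, centre, rng)
        return v / n
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _solid_footprint(shape, spacing, centre_um, axes_um, basis):
    """Bounding-box slice + solid-ellipsoid mask for collision checks."""
    spacing = np.asarray(spacing, float)
    r_bound = float(np.max(axes_um)) + float(spacing.max())
    lo = np.maximum(
        0, np.floor((np.asarray(centre_um) - r_bound) / spacing).astype(int)
    )
    hi = np.minimum(
        np.array(shape),
        np.ceil((np.asarray(centre_um) + r_bound) / spacing).astype(int) + 1,
    )
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * spacing[a] - centre_um[a] for a in range(3)],
        indexing="ij",
    )
    proj = np.stack(grids, axis=-1) @ basis.T
    # one voxel of clearance between neighbouring cells
    inside = np.sum(
        (proj / (np.asarray(axes_um) + spacing.min())) ** 2, axis=-1
    ) <= 1.0
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    return box, inside


def _place_cells(
    params: SceneParams,
    tissue_all: np.ndarray,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> list[_Cell]:
    """Rejection-sample non-overlapping cells inside persistent tissue."""
    spacing = np.asarray(params.spacing)
    # distance (um) to the nearest non-tissue voxel, honouring anisotropy
    dist = ndi.distance_transform_edt(tissue_all, sampling=spacing)
    occupancy = np.zeros(tissue_all.shape, dtype=bool)
    cells: list[_Cell] = []
    next_id = 1
    int_mean, int_sd = params.cell_intensity

    def try_place(label: str, axes, hollow, pieces=None) -> _Cell:
        nonlocal next_id
        r_bound = float(np.max(axes))
        candidates = np.argwhere(dist >= r_bound + 1.0)
        if len(candidates) == 0:
            raise PlacementError(
                f"no tissue voxel can host class {label!r} "
                f"(bounding radius {r_bound:.1f} um)"
            )
        for _ in range(max_retries):
            vox = candidates[rng.integers(len(candidates))]
            centre = vox * spacing
            if label in ELONGATED_CLASSES:
                major = _sample_orientation(params, centre, rng)
            else:
                major = _random_unit(rng)
            basis = _orthonormal_basis(major, rng)
            box, footprint = _solid_footprint(
                tissue_all.shape, spacing, centre, axes, basis
            )
            if np.any(occupancy[box] & footprint):
                continue
            occupancy[box] |= footprint
            channel = CLASS_CHANNEL.get(label, CHANNELS[rng.integers(2)])
            cell = _Cell(
                structure_id=next_id,
                label=label,
                channel=channel,
                centre=centre,
                axes=np.asarray(axes, float),
                basis=basis,
                brightness=float(rng.normal(int_mean, int_sd)),
                hollow=hollow,
                pieces=pieces,
            )
            next_id += 1
            return cell
        raise PlacementError(
            f"could not place class {label!r} after {max_retries} retries; "
            "scene too dense for this class"
        )

    for label in CLASSES:
        n = params.n_cells_per_class.get(label, 0)
        geom = params.class_geometry[label]
        ratio_mean, ratio_sd = params.elongation_by_class[label]
        for _ in range(n):
            major = max(rng.normal(geom.major_mean, geom.major_sd), 1.5)
            ratio = float(np.clip(rng.normal(ratio_mean, ratio_sd), 0.12, 0.95))
            axes = (major, major * ratio, major * ratio)
            cells.append(try_place(label, axes, label in SHELL_CLASSES))
    for _ in range(params.n_faulty):
        n_pieces = int(rng.integers(2, 4))
        pieces = [
            (rng.uniform(-2.5, 2.5, 3), rng.uniform(1.4, 2.4))
            for _ in range(n_pieces)
        ]
        cells.append(
            try_place(FAULTY, (5.0, 5.0, 5.0), hollow=False, pieces=pieces)
        )
    return cells


# ---------------------------------------------------------------------------
# main generator


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render a full synthetic scene; deterministic for a given seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.grid_shape
    spacing = params.spacing
    nt = params.n_frames
    centre = params.centre_um

    # --- static geometry (frame-0 / undrifted coordinates) -----------------
    organoid_masks = [
        _ball_mask(shape, spacing, centre, params.organoid_radius_schedule[t])
        for t in range(nt)
    ]
    # per-frame lumen instance volume with fusion-aware relabelling
    alive_parent = {i + 1: i + 1 for i in range(len(params.lumen_specs))}
    fusions_by_frame: dict[int, list[tuple[int, int]]] = {}
    for frame, a, b in sorted(params.fusion_schedule):
        fusions_by_frame.setdefault(frame, []).append((a, b))

    def root(lid: int) -> int:
        while alive_parent[lid] != lid:
            lid = alive_parent[lid]
        return lid

    lumen_instances = np.zeros((nt, *shape), dtype=np.uint16)
    realized_fusions: list[tuple[int, int, int]] = []
    for t in range(nt):
        for a, b in fusions_by_frame.get(t, []):
            ra, rb = root(a), root(b)
            if ra == rb:
                continue
            alive_parent[rb] = ra
            realized_fusions.append((t, ra, rb))
        vol = lumen_instances[t]
        for i, spec in enumerate(params.lumen_specs):
            lid = i + 1
            if spec.birth_frame > t:
                continue
            r = spec.radius_schedule[t]
            if r <= 0:
                continue
            mask = _ball_mask(shape, spacing, np.asarray(spec.centre), r)
            vol[mask] = root(lid)
        # every instance id must be exactly one connected component and
        # distinct ids must not touch: fusion is realized geometrically
        binary = vol > 0
        cc, n_cc = ndi.label(binary)
        ids = set(np.unique(vol)) - {0}
        if n_cc != len(ids):
            for frame, ra, rb in realized_fusions:
                if frame == t:
                    comp_a = set(np.unique(cc[vol == ra]))
                    if len(comp_a) > 1:
                        raise FusionGeometryError(
                            f"lumens {ra} and {rb} scheduled to fuse at frame "
                            f"{t} are not adjacent"
                        )
            raise FusionGeometryError(
                f"frame {t}: {n_cc} lumen components for {len(ids)} instance "
                "ids (unscheduled contact or fragmented lumen)"
            )

    tissue_all = organoid_masks[0].copy()
    for t in range(nt):
        tissue_all &= organoid_masks[t] & (lumen_instances[t] == 0)

    # --- cells --------------------------------------------------------------
    cells = _place_cells(params, tissue_all, rng)
    dist = ndi.distance_transform_edt(tissue_all, sampling=np.asarray(spacing))

    # per-frame cell centres: optional bounded random walk inside tissue
    centres_by_frame: list[dict[int, np.ndarray]] = []
    current = {c.structure_id: c.centre.copy() for c in cells}
    for t in range(nt):
        if t > 0 and params.cell_jitter_um > 0:
            for c in cells:
                prop = current[c.structure_id] + rng.normal(
                    0, params.cell_jitter_um, 3
                )
                vox = np.round(prop / np.asarray(spacing)).astype(int)
                if (
                    np.all(vox >= 0)
                    and np.all(vox < np.array(shape))
                    and dist[tuple(vox)] >= c.bound_radius + 1.0
                ):
                    current[c.structure_id] = prop
        centres_by_frame.append(
            {sid: pos.copy() for sid, pos in current.items()}
        )

    # --- render frames ------------------------------------------------------
    offsets = np.array(
        [np.asarray(params.drift_per_frame, int) * t for t in range(nt)]
    )
    timelapse = {
        ch: np.zeros((nt, *shape), dtype=np.float32) for ch in CHANNELS
    }
    gt_semantic = np.zeros((nt, *shape), dtype=np.uint8)
    cell_instances = np.zeros((nt, *shape), dtype=np.uint16)
    rows = []
    for t in range(nt):
        lumen = lumen_instances[t] > 0
        tissue = organoid_masks[t] & ~lumen
        semantic = np.zeros(shape, dtype=np.uint8)
        semantic[lumen] = 1
        semantic[tissue] = 2
        intensity = {ch: np.zeros(shape, dtype=np.float32) for ch in CHANNELS}
        for ch in CHANNELS:
            intensity[ch][tissue] = params.tissue_intensity
            intensity[ch][lumen] = params.lumen_intensity
        cvol = cell_instances[t]
        for c in cells:
            pos = centres_by_frame[t][c.structure_id]
            if c.pieces is not None:  # faulty debris: union of small balls
                for off, r in c.pieces:
                    _rasterize_ellipsoid(
                        cvol, spacing, pos + off, (r, r, r),
                        np.eye(3), c.structure_id,
                    )
            else:
                _rasterize_ellipsoid(
                    cvol, spacing, pos, c.axes, c.basis, c.structure_id,
                    hollow_wall_um=params.wall_um if c.hollow else None,
                )
            rows.append(
                {
                    "structure_id": c.structure_id,
                    "frame": t,
                    "class": c.label,
                    "channel": c.channel,
                    "centroid_z_um": pos[0] + offsets[t, 0] * spacing[0],
                    "centroid_y_um": pos[1] + offsets[t, 1] * spacing[1],
                    "centroid_x_um": pos[2] + offsets[t, 2] * spacing[2],
                    "track_id": c.structure_id,
                    "gt_major_um": float(c.axes[0]),
                    "gt_axis_ratio": float(c.axes[1] / c.axes[0]),
                }
            )
        for c in cells:
            vox_mask = cvol == c.structure_id
            for ch in CHANNELS:
                if ch == c.channel:
                    intensity[ch][vox_mask] = np.maximum(
                        intensity[ch][vox_mask], c.brightness
                    )
        # apply cumulative drift, then noise
        off = offsets[t]
        gt_semantic[t] = integer_shift(semantic, off)
        lumen_instances[t] = integer_shift(lumen_instances[t], off)
        cell_instances[t] = integer_shift(cvol, off)
        for ch in CHANNELS:
            vol = integer_shift(intensity[ch], off)
            if params.noise_sd > 0:
                vol = vol + rng.normal(0, params.noise_sd, shape).astype(
                    np.float32
                )
            timelapse[ch][t] = np.clip(vol, 0, None)

    gt_cells = pd.DataFrame(rows)
    scene = SyntheticScene(
        params=params,
        timelapse=timelapse,
        gt_semantic=gt_semantic,
        gt_lumen_instances=lumen_instances,
        gt_cell_instances=cell_instances,
        gt_labels={c.structure_id: c.label for c in cells},
        gt_cells=gt_cells,
        gt_tracks=gt_cells,
        gt_fusions=realized_fusions,
        gt_offsets=offsets,
        gt_orientations={c.structure_id: c.basis[0].copy() for c in cells},
    )
    return scene


# ---------------------------------------------------------------------------
# scene factories used as fixed study conditions


def three_fusion_scene_params(seed: int = 0, noise_sd: float = 3.0) -> SceneParams:
    """A 12-frame scene with four lumens and three scheduled fusions.

    Two lumen pairs fuse at frames 3 and 6; the two merged cavities fuse at
    frame 9, leaving one lumen.  All lumen radii stay >= 18 um so every
    instance clears the 20,000 um^3 lumen volume threshold.
    """
    rA = (18, 20, 22, 27.5, 28, 28, 28, 28, 28, 33, 33, 33)
    rC = (18, 19, 20, 21, 22, 24.5, 27.5, 27.5, 27.5, 33, 33, 33)
    return SceneParams(
        grid_shape=(84, 168, 168),
        spacing=(2.0, 1.0, 1.0),
        n_frames=12,
        frame_interval=1.0,
        organoid_radius_schedule=(66, 67, 68, 69, 70, 71, 72, 73, 74, 76, 77, 78),
        lumen_specs=[
            LumenSpec(0, (84.0, 58.0, 53.0), rA),
            LumenSpec(0, (84.0, 110.0, 53.0), rA),
            LumenSpec(0, (84.0, 58.0, 115.0), rC),
            LumenSpec(0, (84.0, 110.0, 115.0), rC),
        ],
        fusion_schedule=[(3, 1, 2), (6, 3, 4), (9, 1, 3)],
        n_cells_per_class={c: 0 for c in CLASSES},
        noise_sd=noise_sd,
        seed=seed,
    )


def drift_scene_params(
    seed: int = 0,
    drift: tuple[int, int, int] = (1, 2, 3),
    n_frames: int = 10,
    noise_sd: float = 2.0,
) -> SceneParams:
    """Small static organoid translated by a constant integer drift."""
    return SceneParams(
        grid_shape=(32, 96, 96),
        spacing=(2.0, 1.0, 1.0),
        n_frames=n_frames,
        organoid_radius_schedule=tuple([20.0] * n_frames),
        lumen_specs=[
            LumenSpec(0, (24.0, 30.0, 30.0), tuple([8.0] * n_frames))
        ],
        n_cells_per_class={c: 0 for c in CLASSES},
        drift_per_frame=drift,
        noise_sd=noise_sd,
        seed=seed,
    )


def demux_scene_params(
    seed: int = 0,
    n_per_class: int = 20,
    n_faulty: int = 12,
    n_frames: int = 4,
    noise_sd: float = 3.0,
) -> SceneParams:
    """Mosaic-label scene: five classes + debris, for demultiplexer training."""
    n_frames = int(n_frames)
    return SceneParams(
        grid_shape=(64, 160, 160),
        spacing=(2.0, 1.0, 1.0),
        n_frames=n_frames,
        organoid_radius_schedule=tuple([68.0] * n_frames),
        lumen_specs=[],
        n_cells_per_class={c: n_per_class for c in CLASSES},
        n_faulty=n_faulty,
        cell_jitter_um=0.4,
        noise_sd=noise_sd,
        seed=seed,
    )


def alignment_scene_params(
    seed: int = 0,
    radial_fraction: float = 1.0,
    nonradial_orientation: str = "random",
    n_actin: int = 60,
) -> SceneParams:
    """Single-frame isotropic scene of elongated actin cells on a sphere."""
    return SceneParams(
        grid_shape=(96, 96, 96),
        spacing=(1.0, 1.0, 1.0),
        n_frames=1,
        organoid_radius_schedule=(42.0,),
        lumen_specs=[],
        n_cells_per_class={
            "histone": 0, "lamin": 0, "actin": n_actin,
            "tubulin": 0, "membrane": 0,
        },
        radial_fraction=radial_fraction,
        nonradial_orientation=nonradial_orientation,
        noise_sd=2.0,
        seed=seed,
    )


def tracking_scene_params(
    seed: int = 0,
    n_cells: int = 10,
    n_frames: int = 6,
    jitter_um: float = 1.0,
) -> SceneParams:
    """Scene of large, slowly wandering cells for tracklet validation.

    Cell volumes (~2,600 um^3) clear the 1,444 um^3 cell-mask filter at the
    reference threshold.
    """
    return SceneParams(
        grid_shape=(48, 112, 112),
        spacing=(2.0, 1.0, 1.0),
        n_frames=n_frames,
        organoid_radius_schedule=tuple([45.0] * n_frames),
        lumen_specs=[],
        n_cells_per_class={
            "histone": n_cells, "lamin": 0, "actin": 0,
            "tubulin": 0, "membrane": 0,
        },
        class_geometry={
            **DEFAULT_GEOMETRY,
            "histone": ClassGeometry(9.0, 0.4),
        },
        elongation_by_class={
            **DEFAULT_ELONGATION,
            "histone": (0.92, 0.02),
        },
        cell_jitter_um=jitter_um,
        noise_sd=2.0,
        seed=seed,
    )


def tissue_scene_params(seed: int = 0, n_frames: int = 2,
                        noise_sd: float = 3.0) -> SceneParams:
    """Small scene for tissue-segmentation training/evaluation."""
    return SceneParams(
        grid_shape=(24, 72, 72),
        spacing=(2.0, 1.0, 1.0),
        n_frames=n_frames,
        organoid_radius_schedule=tuple(
            np.linspace(24.0, 26.0, n_frames)
        ),
        lumen_specs=[
            LumenSpec(
                0, (24.0, 36.0, 36.0),
                tuple(np.linspace(11.0, 12.0, n_frames)),
            )
        ],
        n_cells_per_class={c: 0 for c in CLASSES},
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence


def write_scene(
    scene: SyntheticScene, out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Write a scene to disk: per-channel/frame TIFFs, mask TIFFs, CSV truth.

    Returns the manifest dict (also written as ``manifest.json``).
    Round-trip via :func:`read_scene` reproduces all arrays bit-exactly.
    """
    import tifffile

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    (out / "intensity").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    nt = scene.params.n_frames
    for ch, stack in scene.timelapse.items():
        for t in range(nt):
            tifffile.imwrite(
                out / "intensity" / f"{ch}_t{t:04d}.tif", stack[t]
            )
    mask_arrays = {
        "semantic": scene.gt_semantic,
        "lumen_instances": scene.gt_lumen_instances,
        "cell_instances": scene.gt_cell_instances,
    }
    for name, arr in mask_arrays.items():
        for t in range(nt):
            tifffile.imwrite(out / "masks" / f"{name}_t{t:04d}.tif", arr[t])
    scene.gt_cells.to_csv(out / "tables" / "cells.csv", index=False)
    pd.DataFrame(
        scene.gt_fusions, columns=["frame", "surviving", "absorbed"]
    ).to_csv(out / "tables" / "fusions.csv", index=False)
    pd.DataFrame(
        scene.gt_offsets, columns=["dz", "dy", "dx"]
    ).assign(frame=range(nt)).to_csv(
        out / "tables" / "offsets.csv", index=False
    )
    manifest = {
        "spacing_um": list(scene.params.spacing),
        "frame_interval_h": scene.params.frame_interval,
        "n_frames": nt,
        "grid_shape": list(scene.params.grid_shape),
        "channels": list(scene.timelapse),
        "seed": scene.params.seed,
        "classes": {str(k): v for k, v in scene.gt_labels.items()},
        "offset_convention": (
            "gt_offsets[t] is the cumulative integer (dz,dy,dx) voxel drift "
            "applied to frame t; registration offsets of -gt_offsets[t] map "
            "frame t back onto frame 0"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_scene_arrays(out_dir: str | Path):
    """Read back intensity/mask arrays written by :func:`write_scene`."""
    import tifffile

    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    nt = manifest["n_frames"]
    timelapse = {
        ch: np.stack(
            [
                tifffile.imread(out / "intensity" / f"{ch}_t{t:04d}.tif")
                for t in range(nt)
            ]
        )
        for ch in manifest["channels"]
    }
    masks = {
        name: np.stack(
            [
                tifffile.imread(out / "masks" / f"{name}_t{t:04d}.tif")
                for t in range(nt)
            ]
        )
        for name in ("semantic", "lumen_instances", "cell_instances")
    }
    return manifest, timelapse, masks
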