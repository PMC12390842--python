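"""Random-forest tissue segmentation and tissue-scale quantification.

Semantic classes: 0 = background, 1 = lumen, 2 = organoid tissue.  Pixels
are classified per z-slice from multiscale intensity/edge/texture features
of the summed fluorescence channels, then post-processed in 3D (smoothing,
slice-wise morphology, convex-hull consistency, largest-object selection)
and, for time series, stabilised with a temporal median filter, binary
opening and a minimum lumen volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import multiscale_basic_features
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, convex_hull_image, disk
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

BACKGROUND, LUMEN, TISSUE = 0, 1, 2
#: minimum lumen volume retained after time-series post-processing (um^3)
LUMEN_MIN_VOLUME_UM3 = 20_000.0


def multiscale_features(
    slice2d: np.ndarray, sigma_min: float = 1.0, sigma_max: float = 64.0
) -> np.ndarray:
    """Per-pixel intensity/edge/texture features on a geometric sigma ladder.

    Texture features are the two eigenvalues of the Gaussian Hessian, so a
    ladder of n sigmas yields ``4*n`` features per pixel.
    """
    slice2d = np.asarray(slice2d)
    if slice2d.ndim != 2:
        raise ValueError("multiscale_features expects a 2D image")
    return multiscale_basic_features(
        slice2d.astype(np.float32),
        intensity=True,
        edges=True,
        texture=True,
        sigma_min=sigma_min,
        sigma_max=sigma_max,
    )


def n_feature_channels(sigma_min: float = 1.0, sigma_max: float = 64.0) -> int:
    n_sigma = int(np.log2(sigma_max / sigma_min)) + 1
    return 4 * n_sigma


@dataclass
class BoxAnnotation:
    """A 2D box on one z-slice of one frame, labelled with a single class."""

    frame: int
    z: int
    cls: int  # 0 background, 1 lumen, 2 tissue
    y0: int
    y1: int
    x0: int
    x1: int


@dataclass
class TissueClassifier:
    forest: RandomForestClassifier
    sigma_min: float
    sigma_max: float
    holdout_accuracy: dict[int, float]


def summed_channels(timelapse: dict[str, np.ndarray]) -> np.ndarray:
    """Feature input image: sum of both fluorescence channels."""
    stacks = list(timelapse.values())
    out = stacks[0].astype(np.float32).copy()
    for s in stacks[1:]:
        out += s
    return out


def annotations_from_ground_truth(
    gt_semantic: np.ndarray,
    n_boxes_per_class: int = 8,
    box_half: int = 3,
    seed: int = 0,
) -> list[BoxAnnotation]:
    """Sample pure-class training boxes from a ground-truth semantic movie.

    Boxes are centred on voxels whose in-slice neighbourhood is entirely one
    class, emulating sparse hand-drawn bounding-box annotations.
    """
    rng = np.random.default_rng(seed)
    boxes: list[BoxAnnotation] = []
    nt = gt_semantic.shape[0]
    for cls in (BACKGROUND, LUMEN, TISSUE):
        placed = 0
        guard = 0
        while placed < n_boxes_per_class and guard < 10_000:
            guard += 1
            t = int(rng.integers(nt))
            sl = gt_semantic[t]
            zs = np.unique(np.argwhere(sl == cls)[:, 0]) if np.any(
                sl == cls
            ) else []
            if len(zs) == 0:
                continue
            z = int(rng.choice(zs))
            plane = sl[z]
            cand = np.argwhere(plane == cls)
            y, x = cand[rng.integers(len(cand))]
            y0, y1 = y - box_half, y + box_half + 1
            x0, x1 = x - box_half, x + box_half + 1
            if y0 < 0 or x0 < 0 or y1 > plane.shape[0] or x1 > plane.shape[1]:
                continue
            if np.all(plane[y0:y1, x0:x1] == cls):
                boxes.append(BoxAnnotation(t, z, cls, y0, y1, x0, x1))
                placed += 1
        if placed == 0:
            raise ValueError(f"class {cls} not found in ground truth")
    return boxes


def boxes_to_csv(annotations: list[BoxAnnotation], path) -> None:
    pd.DataFrame([vars(b) for b in annotations]).to_csv(path, index=False)


def boxes_from_csv(path) -> list[BoxAnnotation]:
    table = pd.read_csv(path)
    return [BoxAnnotation(**{k: int(v) for k, v in row.items()})
            for row in table.to_dict("records")]


def _gather_training_pixels(summed, annotations, sigma_min, sigma_max):
    X, y = [], []
    feats_cache: dict[tuple[int, int], np.ndarray] = {}
    for box in annotations:
        key = (box.frame, box.z)
        if key not in feats_cache:
            feats_cache[key] = multiscale_features(
                summed[box.frame, box.z], sigma_min, sigma_max
            )
        f = feats_cache[key][box.y0: box.y1, box.x0: box.x1]
        X.append(f.reshape(-1, f.shape[-1]))
        y.append(np.full(X[-1].shape[0], box.cls))
    return np.concatenate(X), np.concatenate(y)


def train_tissue_rf(
    summed: np.ndarray,
    annotations: list[BoxAnnotation],
    n_estimators: int = 50,
    max_depth: int = 25,
    max_samples: float = 0.05,
    holdout_fraction: float = 0.25,
    sigma_min: float = 1.0,
    sigma_max: float = 64.0,
    seed: int = 0,
) -> TissueClassifier:
    """Train the pixel classifier on annotated boxes; report held-out accuracy.

    Raises if any of the three classes is missing from the annotations.
    """
    present = {b.cls for b in annotations}
    if present != {BACKGROUND, LUMEN, TISSUE}:
        raise ValueError(
            f"annotations must cover all three classes, got {sorted(present)}"
        )
    X, y = _gather_training_pixels(summed, annotations, sigma_min, sigma_max)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    n_hold = max(1, int(holdout_fraction * len(y)))
    hold, train = idx[:n_hold], idx[n_hold:]
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_samples=max_samples,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X[train], y[train])
    pred = forest.predict(X[hold])
    acc = {
        int(cls): float(np.mean(pred[y[hold] == cls] == cls))
        for cls in np.unique(y[hold])
    }
    logger.info("tissue RF held-out per-class accuracy: %s", acc)
    return TissueClassifier(forest, sigma_min, sigma_max, acc)


def predict_semantic(
    volume: np.ndarray, clf: TissueClassifier
) -> np.ndarray:
    """Classify every pixel of a 3D volume slice by slice."""
    out = np.zeros(volume.shape, dtype=np.uint8)
    for z in range(volume.shape[0]):
        f = multiscale_features(volume[z], clf.sigma_min, clf.sigma_max)
        flat = f.reshape(-1, f.shape[-1])
        if flat.shape[1] != clf.forest.n_features_in_:
            raise ValueError("feature dimension mismatch with classifier")
        out[z] = clf.forest.predict(flat).reshape(volume[z].shape)
    return out


def postprocess_semantic(
    raw: np.ndarray,
    spacing,
    smooth_sigma_um: float = 2.776,
    disk_radius: int = 3,
) -> np.ndarray:
    """3D smoothing + slice-wise morphological clean-up of a semantic mask.

    Steps: (i) Gaussian smoothing of each binary class mask (isotropic in
    physical units) and argmax recombination; (ii) per z-slice: lumen closing
    with a disk, lumen hole filling, background enclosed by the organoid
    reassigned to lumen, lumen outside the organoid's convex hull reassigned
    to background; (iii) keep only the largest connected non-background
    object.
    """
    spacing = np.asarray(spacing, float)
    sigma_vox = smooth_sigma_um / spacing
    smoothed = np.stack(
        [
            ndi.gaussian_filter((raw == cls).astype(np.float32), sigma_vox)
            for cls in (BACKGROUND, LUMEN, TISSUE)
        ]
    )
    mask = np.argmax(smoothed, axis=0).astype(np.uint8)

    selem = disk(disk_radius)
    for z in range(mask.shape[0]):
        plane = mask[z]
        lumen = plane == LUMEN
        tissue = plane == TISSUE
        lumen = closing(lumen, selem).astype(bool)
        lumen = ndi.binary_fill_holes(lumen)
        organoid = ndi.binary_fill_holes(tissue | lumen)
        # background enclosed by the organoid becomes lumen
        lumen |= organoid & ~tissue
        if np.any(tissue):
            hull = convex_hull_image(tissue)
            lumen &= hull
        else:
            lumen[:] = False
        out = np.zeros_like(plane)
        out[lumen] = LUMEN
        out[tissue & ~lumen] = TISSUE
        mask[z] = out

    organoid3d = mask != BACKGROUND
    cc = cc_label(organoid3d)
    if cc.max() == 0:
        raise ValueError("post-processing removed the whole organoid")
    largest = np.argmax(np.bincount(cc.ravel())[1:]) + 1
    mask[cc != largest] = BACKGROUND
    return mask


def postprocess_lumen_timeseries(
    semantic_series: np.ndarray,
    spacing,
    opening_iterations: int = 4,
    temporal_size: int = 5,
    min_volume_um3: float = LUMEN_MIN_VOLUME_UM3,
) -> np.ndarray:
    """Temporally stabilised per-frame lumen instance masks.

    Applies a temporal median filter (size ``temporal_size`` along t, 1 along
    z/y/x) to the binary lumen masks, a per-frame binary opening, connected
    component labelling, and removal of components below ``min_volume_um3``.
    """
    spacing = np.asarray(spacing, float)
    voxel_vol = float(np.prod(spacing))
    lumen = (semantic_series == LUMEN).astype(np.uint8)
    nt = lumen.shape[0]
    size_t = min(temporal_size, nt)
    if size_t % 2 == 0:
        size_t = max(1, size_t - 1)
    if size_t > 1:
        lumen = ndi.median_filter(lumen, size=(size_t, 1, 1, 1))
    out = np.zeros(lumen.shape, dtype=np.uint16)
    min_vox = min_volume_um3 / voxel_vol
    for t in range(nt):
        frame = lumen[t].astype(bool)
        if opening_iterations > 0 and np.any(frame):
            frame = ndi.binary_opening(frame, iterations=opening_iterations)
        cc, n = ndi.label(frame)
        if n == 0:
            continue
        sizes = np.bincount(cc.ravel())
        keep = np.flatnonzero(sizes >= min_vox)
        keep = keep[keep != 0]
        relabel = np.zeros(n + 1, dtype=np.uint16)
        relabel[keep] = np.arange(1, len(keep) + 1)
        out[t] = relabel[cc]
    return out


def quantify_tissue(
    semantic_series: np.ndarray,
    lumen_instances: np.ndarray,
    spacing,
) -> pd.DataFrame:
    """Per-frame organoid volume plus lumen count/volume/major-axis length.

    Returns one row per lumen per frame (frames without lumens get a single
    row with ``lumen_id`` = NaN), with ``organoid_volume_um3`` and
    ``lumen_count`` repeated per frame.
    """
    spacing = tuple(float(s) for s in spacing)
    voxel_vol = float(np.prod(spacing))
    rows = []
    for t in range(semantic_series.shape[0]):
        organoid_vol = float(
            np.count_nonzero(semantic_series[t] != BACKGROUND) * voxel_vol
        )
        props = regionprops(lumen_instances[t].astype(int), spacing=spacing)
        base = {
            "frame": t,
            "organoid_volume_um3": organoid_vol,
            "lumen_count": len(props),
        }
        if not props:
            rows.append({**base, "lumen_id": np.nan,
                         "lumen_volume_um3": np.nan,
                         "lumen_major_axis_um": np.nan})
        for p in props:
            rows.append(
                {
                    **base,
                    "lumen_id": p.label,
                    "lumen_volume_um3": float(p.area),
                    "lumen_major_axis_um": float(p.axis_major_length),
                }
            )
    return pd.DataFrame(rows)
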