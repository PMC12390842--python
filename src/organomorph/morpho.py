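"""Morphometric feature extraction, quality control and label demultiplexing.

Each segmented subcellular structure gets one feature row per frame
(size, surface, shape, intensity, position and second-moment measurements,
in physical units after resampling to an isotropic working voxel size).
A random-forest classifier then demultiplexes the two-channel mosaic into
the five label classes (histone, lamin, actin, tubulin, membrane) plus a
"faulty" debris class, followed by a channel-consistency filter that drops
predictions that could not have originated from the structure's channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import marching_cubes, mesh_surface_area, regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)

from .synthgen import CLASSES, FAULTY

logger = logging.getLogger(__name__)

#: isotropic working voxel size for morphometrics (um)
ISO_VOXEL_UM = 0.694
#: minimum structure size at the working voxel size (voxels)
MIN_VOLUME_VOXELS = 100
#: minimum maximum-intensity for a structure to pass QC
MIN_MAX_INTENSITY = 20.0

LABELS = (*CLASSES, FAULTY)
#: labels that can legitimately appear in each channel ("faulty" in both)
CHANNEL_LABELS = {
    "gfp": frozenset({"actin", "histone", FAULTY}),
    "rfp": frozenset({"lamin", "membrane", "tubulin", FAULTY}),
}

_ID_COLUMNS = ("structure_id", "frame", "channel", "label", "predicted_label",
               "qc_pass")


def _resample_iso(instances, intensity, spacing, iso):
    factors = np.asarray(spacing, float) / iso
    inst = ndi.zoom(instances, factors, order=0, prefilter=False)
    inten = ndi.zoom(intensity.astype(np.float32), factors, order=1)
    return inst, inten


def _surface_area(mask_iso: np.ndarray, iso: float) -> float:
    padded = np.pad(mask_iso.astype(np.uint8), 1)
    try:
        verts, faces, _, _ = marching_cubes(
            padded, level=0.5, spacing=(iso, iso, iso)
        )
    except (ValueError, RuntimeError):
        return np.nan
    return float(mesh_surface_area(verts, faces))


def extract_features(
    instances: np.ndarray,
    intensity: np.ndarray,
    spacing,
    channel: str = "gfp",
    frame: int = 0,
    iso_voxel_um: float = ISO_VOXEL_UM,
    min_volume_voxels: int = MIN_VOLUME_VOXELS,
) -> pd.DataFrame:
    """One feature row per instance, measured at an isotropic voxel size.

    Masks are resampled with nearest-neighbour and intensities with linear
    interpolation to ``iso_voxel_um``; instances smaller than
    ``min_volume_voxels`` at that resolution are dropped.  An empty mask
    yields an empty table.
    """
    if instances.shape != intensity.shape:
        raise ValueError("instance and intensity shapes differ")
    inst, inten = _resample_iso(instances, intensity, spacing, iso_voxel_um)
    voxel_vol = iso_voxel_um**3
    rows = []
    for p in regionprops(inst.astype(int), intensity_image=inten):
        if p.num_pixels < min_volume_voxels:
            continue
        try:
            major = float(p.axis_major_length) * iso_voxel_um
            minor = float(p.axis_minor_length) * iso_voxel_um
        except ValueError:
            major = minor = np.nan
        try:
            solidity = float(p.solidity)
        except Exception:
            solidity = np.nan
        sub = p.image
        area = _surface_area(sub, iso_voxel_um)
        volume = p.num_pixels * voxel_vol
        sphericity = (
            np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
            if area and area > 0
            else np.nan
        )
        inert = np.asarray(p.inertia_tensor_eigvals) * iso_voxel_um**2
        vals = p.image_intensity[p.image]
        rows.append(
            {
                "structure_id": int(p.label),
                "frame": int(frame),
                "channel": channel,
                "centroid_z_um": p.centroid[0] * iso_voxel_um,
                "centroid_y_um": p.centroid[1] * iso_voxel_um,
                "centroid_x_um": p.centroid[2] * iso_voxel_um,
                "volume_voxels": int(p.num_pixels),
                "volume_um3": volume,
                "surface_area_um2": area,
                "axis_major_um": major,
                "axis_minor_um": minor,
                "axis_ratio": minor / major if major and major > 0 else np.nan,
                "sphericity": sphericity,
                "solidity": solidity,
                "intensity_mean": float(np.mean(vals)),
                "intensity_max": float(np.max(vals)),
                "intensity_sd": float(np.std(vals)),
                "inertia_ev0": inert[0],
                "inertia_ev1": inert[1],
                "inertia_ev2": inert[2],
            }
        )
    return pd.DataFrame(rows)


def extract_scene_features(scene, iso_voxel_um: float = ISO_VOXEL_UM,
                           frames=None) -> pd.DataFrame:
    """Per-frame features of a synthetic scene's cell instances, with truth.

    Structures are measured against the intensity volume of their own
    channel; the returned table carries the ground-truth ``label`` column
    for training/validating the demultiplexer.
    """
    from .synthgen import CLASS_CHANNEL

    frames = range(scene.params.n_frames) if frames is None else frames
    tables = []
    id_channel = {
        sid: CLASS_CHANNEL.get(lbl, "gfp")
        for sid, lbl in scene.gt_labels.items()
    }
    for t in frames:
        inst = scene.gt_cell_instances[t]
        for ch in scene.timelapse:
            ids = [sid for sid, c in id_channel.items() if c == ch]
            if not ids:
                continue
            sel = np.where(np.isin(inst, ids), inst, 0)
            tab = extract_features(
                sel, scene.timelapse[ch][t], scene.params.spacing,
                channel=ch, frame=t, iso_voxel_um=iso_voxel_um,
            )
            if len(tab):
                tab["label"] = tab["structure_id"].map(scene.gt_labels)
                tables.append(tab)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def qc_filter(
    table: pd.DataFrame,
    min_volume_voxels: int = MIN_VOLUME_VOXELS,
    min_max_intensity: float = MIN_MAX_INTENSITY,
) -> pd.DataFrame:
    """Drop rows failing the volume/intensity thresholds or containing NaNs.

    Thresholds are strict ("less than"): a row at exactly the threshold is
    kept.  Removal counts are logged per reason.
    """
    if table.empty:
        return table
    feature_cols = [c for c in table.columns if c not in _ID_COLUMNS]
    small = table["volume_voxels"] < min_volume_voxels
    dim = table["intensity_max"] < min_max_intensity
    has_nan = table[feature_cols].isna().any(axis=1)
    keep = ~(small | dim | has_nan)
    logger.info(
        "QC: removed %d small, %d dim, %d with NaNs of %d rows",
        int(small.sum()), int(dim.sum()), int(has_nan.sum()), len(table),
    )
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# demultiplexer


def demux_feature_columns(table: pd.DataFrame) -> list[str]:
    """All numeric morphometrics plus the channel indicator."""
    cols = [
        c
        for c in table.columns
        if c not in _ID_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]
    return cols


@dataclass
class DemuxModel:
    forest: RandomForestClassifier
    feature_columns: list[str]
    labels: tuple[str, ...]
    grid_results: pd.DataFrame
    best_params: dict
    test_accuracy: float
    confusion: np.ndarray | None = None
    per_marker_precision: dict[str, float] = field(default_factory=dict)


def _design(table: pd.DataFrame, feature_columns=None):
    tab = table.copy()
    tab["channel_is_gfp"] = (tab["channel"] == "gfp").astype(float)
    if feature_columns is None:
        feature_columns = demux_feature_columns(tab)
    missing = [c for c in feature_columns if c not in tab.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing {missing}")
    X = tab[feature_columns].to_numpy(dtype=float)
    return X, feature_columns


DEFAULT_GRID = {"n_estimators": [50, 100, 200],
                "max_depth": [5, 10, 20, None]}


def train_demux(
    table: pd.DataFrame,
    test_fraction: float = 0.1,
    seed: int = 0,
    grid: dict | None = None,
    cv: int = 4,
) -> DemuxModel:
    """Grid-searched random-forest demultiplexer.

    The labelled table is split 90/10 (stratified); tree count and depth are
    selected by ``cv``-fold cross-validation on the training split, the best
    model is refit on the whole training split, and test accuracy reported.
    """
    if "label" not in table.columns:
        raise ValueError("table must carry a 'label' column")
    counts = table["label"].value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 examples, got {dict(counts)}")
    X, feature_columns = _design(table)
    y = table["label"].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if set(np.unique(y_tr)) != set(np.unique(y)):
        raise ValueError("a class is absent from the training split")
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        grid or DEFAULT_GRID,
        cv=cv,
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    results = pd.DataFrame(search.cv_results_)[
        ["param_n_estimators", "param_max_depth", "mean_test_score"]
    ]
    best = search.best_estimator_
    acc = float(np.mean(best.predict(X_te) == y_te))
    logger.info("demux test accuracy %.3f with %s", acc, search.best_params_)
    return DemuxModel(
        forest=best,
        feature_columns=feature_columns,
        labels=LABELS,
        grid_results=results,
        best_params=dict(search.best_params_),
        test_accuracy=acc,
    )


def crossval_confusion(
    table: pd.DataFrame,
    model: DemuxModel,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float], list[str]]:
    """Stratified k-fold summed confusion matrix and per-marker precision.

    The model (with its selected hyper-parameters) is retrained on each
    fold's training part; fold-wise test confusions are summed.  Faulty-class
    rows/columns are excluded before computing per-marker precision.
    """
    counts = table["label"].value_counts()
    if (counts < k).any():
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV")
    X, _ = _design(table, model.feature_columns)
    y = table["label"].to_numpy()
    classes = sorted(np.unique(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    total = np.zeros((len(classes), len(classes)), dtype=int)
    for tr, te in skf.split(X, y):
        clf = RandomForestClassifier(
            random_state=seed, n_jobs=1, **model.best_params
        )
        clf.fit(X[tr], y[tr])
        total += confusion_matrix(y[te], clf.predict(X[te]), labels=classes)
    keep = [i for i, c in enumerate(classes) if c != FAULTY]
    markers = [classes[i] for i in keep]
    sub = total[np.ix_(keep, keep)]
    precision = {}
    for j, marker in enumerate(markers):
        denom = sub[:, j].sum()
        precision[marker] = float(sub[j, j] / denom) if denom else np.nan
    return total, precision, classes


def demux_predict(model: DemuxModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predict one label per structure and apply the channel filter.

    Structures whose predicted label could not have been imaged in their
    channel are removed (wrong-channel predictions), mirroring the removal
    of impossible label/channel combinations.
    """
    X, _ = _design(table, model.feature_columns)
    out = table.copy()
    out["predicted_label"] = model.forest.predict(X)
    consistent = [
        row.predicted_label in CHANNEL_LABELS[row.channel]
        for row in out.itertuples()
    ]
    out = out[np.asarray(consistent)].reset_index(drop=True)
    demuxed = out[out["predicted_label"] != FAULTY].reset_index(drop=True)
    if demuxed.empty:
        logger.warning("all structures predicted faulty; empty demux result")
    return out
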