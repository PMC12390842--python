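"""Track-derived motion statistics.

Radial coordination: per cell and frame, the cosine of the angle between
the outward vector (cell centroid minus organoid centre of mass) and the
cell's velocity over a lookback window; +1 = coherent outward motion,
-1 = inward.  Smoothed velocity/direction fields support stream/quiver-style
exports: rolling-mean-smoothed centroids, displacement velocities, and
z / xy direction angles normalized to [0, 1] for display tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("track_id", "frame", "z", "y", "x")


def organoid_center_of_mass(masks: np.ndarray, spacing) -> pd.DataFrame:
    """Per-frame centre of mass (um) of a binary/semantic mask movie."""
    spacing = np.asarray(spacing, float)
    rows = []
    for t in range(masks.shape[0]):
        com = ndi.center_of_mass(masks[t] > 0)
        rows.append(
            {"frame": t, "z": com[0] * spacing[0], "y": com[1] * spacing[1],
             "x": com[2] * spacing[2]}
        )
    return pd.DataFrame(rows)


def radial_coordination(
    tracks: pd.DataFrame,
    com: pd.DataFrame,
    frame_interval: float = 1.0,
    lookback_hours: float = 24.0,
) -> pd.DataFrame:
    """Per-cell, per-frame radial coordination score in [-1, 1].

    Velocity is the displacement over the track's history up to
    ``lookback_hours`` back; the score is the cosine between the outward
    radius (centroid - centre of mass) and that velocity.  Zero-velocity
    observations are excluded (``score`` NaN) and counted in the log.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    com_by_frame = com.set_index("frame")[["z", "y", "x"]]
    lookback_frames = max(1, int(round(lookback_hours / frame_interval)))
    rows = []
    n_zero = 0
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        pos = grp[["z", "y", "x"]].to_numpy(dtype=float)
        frames = grp["frame"].to_numpy()
        for i in range(1, len(grp)):
            j = 0
            for k in range(i - 1, -1, -1):
                if frames[i] - frames[k] <= lookback_frames:
                    j = k
                else:
                    break
            dt = (frames[i] - frames[j]) * frame_interval
            if dt <= 0:
                continue
            vel = (pos[i] - pos[j]) / dt
            if frames[i] not in com_by_frame.index:
                continue
            radial = pos[i] - com_by_frame.loc[frames[i]].to_numpy()
            nv, nr = np.linalg.norm(vel), np.linalg.norm(radial)
            if nv < 1e-12 or nr < 1e-12:
                n_zero += 1
                score = np.nan
            else:
                score = float(vel @ radial / (nv * nr))
            rows.append(
                {"track_id": tid, "frame": int(frames[i]), "score": score,
                 "speed_um_per_h": float(nv)}
            )
    if n_zero:
        logger.info("radial coordination: %d zero-velocity samples excluded",
                    n_zero)
    return pd.DataFrame(rows)


def smoothed_velocities(
    tracks: pd.DataFrame,
    frame_interval: float = 1.0,
    window: int = 10,
    min_periods: int = 1,
    display_lookback_frames: int = 5,
) -> pd.DataFrame:
    """Rolling-mean-smoothed centroids, velocities and direction angles.

    Velocities (u, v, w) = (x, y, z) displacement of the smoothed centroid
    over the previous ``display_lookback_frames`` frames (or the available
    history), per hour.  ``angle_z = atan2(w, sqrt(u^2+v^2))`` and
    ``angle_xy = atan2(u, v)``; both are min-max normalized to [0, 1] in the
    ``*_norm`` display columns.
    """
    out = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame").reset_index(drop=True)
        sm = (
            grp[["z", "y", "x"]]
            .rolling(window, min_periods=min_periods)
            .mean()
            .to_numpy()
        )
        frames = grp["frame"].to_numpy()
        for i in range(1, len(grp)):
            j = max(0, i - display_lookback_frames)
            dt = (frames[i] - frames[j]) * frame_interval
            if dt <= 0:
                continue
            dz, dy, dx = (sm[i] - sm[j]) / dt
            u, v, w = dx, dy, dz
            out.append(
                {
                    "track_id": tid,
                    "frame": int(frames[i]),
                    "u": u,
                    "v": v,
                    "w": w,
                    "angle_z": float(np.arctan2(w, np.hypot(u, v))),
                    "angle_xy": float(np.arctan2(u, v)),
                }
            )
    table = pd.DataFrame(
        out, columns=["track_id", "frame", "u", "v", "w", "angle_z",
                      "angle_xy"]
    )
    for col in ("angle_z", "angle_xy"):
        vals = table[col]
        span = vals.max() - vals.min()
        table[col + "_norm"] = (
            (vals - vals.min()) / span if span > 0 else 0.0 * vals
        )
    return table
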