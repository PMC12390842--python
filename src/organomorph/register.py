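"""Temporal drift correction by multi-frame phase cross-correlation.

Each pairwise translation is estimated from the three axis-wise
maximum-intensity projections of the two volumes: the 2D phase-correlation
shift of each projection constrains two of the three axes, and the two
estimates available per axis are averaged.  Per-frame offsets are then
composed from all pairwise estimates inside a sliding window of consecutive
frames, rounded to integers, and applied to every channel and mask with
zero padding so no voxels are lost.

Sign convention: ``offsets[t]`` is the estimated cumulative displacement of
frame ``t`` relative to frame 0 (an object drifting by ``+d`` voxels per
frame yields ``offsets[t] = t*d``); :func:`apply_offsets` translates frame
``t`` by ``-offsets[t]`` to move it into the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation


@dataclass
class RegistrationOffsets:
    """Integer per-frame translations plus the padding that preserves data."""

    offsets: np.ndarray  # (n_frames, 3) int, (dz, dy, dx)
    padding: np.ndarray  # (3, 2) int, (before, after) per axis

    @property
    def n_frames(self) -> int:
        return len(self.offsets)


def pairwise_shift(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Displacement (dz, dy, dx) of ``frame_b`` relative to ``frame_a``.

    ``frame_b == roll(frame_a, s)`` returns ``s``; translating ``frame_b``
    by ``-s`` maps it onto ``frame_a``.  Uses the mean 2D
    phase-cross-correlation shift of the three axis-wise maximum-intensity
    projections; each spatial axis is covered by two projections and the two
    estimates are averaged.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have equal shapes")
    if frame_a.ndim != 3:
        raise ValueError("expected single-channel 3D volumes")
    if not np.any(frame_a) or not np.any(frame_b):
        raise ValueError("phase correlation undefined for an all-zero frame")
    est = np.zeros(3)
    hits = np.zeros(3)
    for proj_axis in range(3):
        pa = frame_a.max(axis=proj_axis)
        pb = frame_b.max(axis=proj_axis)
        shift2d, _, _ = phase_cross_correlation(pa, pb, upsample_factor=4)
        kept = [ax for ax in range(3) if ax != proj_axis]
        for k, ax in enumerate(kept):
            # pcc reports the correction; negate to get the displacement
            est[ax] += -shift2d[k]
            hits[ax] += 1
    return est / hits


def sequence_offsets(
    frames: list[np.ndarray] | np.ndarray, window: int = 3
) -> RegistrationOffsets:
    """Per-frame integer offsets from windowed multi-frame comparisons.

    All ordered frame pairs inside each sliding window of ``window``
    consecutive frames are phase-correlated.  A pair ``(i, j)`` measures the
    summed drift over steps ``i+1..j``; every step it spans receives the
    implied mean per-step increment, and the per-step increments are averaged
    over all covering pairs before cumulative summation and rounding.
    """
    frames = [np.asarray(f) for f in frames]
    nt = len(frames)
    if nt < 2:
        raise ValueError("need at least 2 frames")
    if window < 2:
        raise ValueError("window must be >= 2")
    window = min(window, nt)
    seen: set[tuple[int, int]] = set()
    step_sum = np.zeros((nt, 3))
    step_n = np.zeros(nt)
    for start in range(nt - window + 1):
        members = range(start, start + window)
        for i in members:
            for j in members:
                if i >= j or (i, j) in seen:
                    continue
                seen.add((i, j))
                d = pairwise_shift(frames[i], frames[j])  # drift over i..j
                for t in range(i + 1, j + 1):
                    step_sum[t] += d / (j - i)
                    step_n[t] += 1
    steps = np.zeros((nt, 3))
    valid = step_n > 0
    steps[valid] = step_sum[valid] / step_n[valid, None]
    drift = np.cumsum(steps, axis=0)
    offsets = np.round(drift).astype(int)
    # frames are translated by -offsets[t]; pad so nothing falls off
    pad_before = np.maximum(0, offsets.max(axis=0))
    pad_after = np.maximum(0, -offsets.min(axis=0))
    padding = np.stack([pad_before, pad_after], axis=1)
    return RegistrationOffsets(offsets=offsets, padding=padding)


def _shift_into(padded_shape, frame, offset, pad_before):
    out = np.zeros(padded_shape, dtype=frame.dtype)
    idx = []
    for ax in range(3):
        start = pad_before[ax] - int(offset[ax])
        idx.append(slice(start, start + frame.shape[ax]))
    out[tuple(idx)] = frame
    return out


def apply_offsets(
    timelapse: dict[str, np.ndarray],
    offsets: RegistrationOffsets,
    masks: dict[str, np.ndarray] | None = None,
):
    """Apply integer offsets plus padding to all channels and masks.

    ``timelapse`` maps channel -> (t, z, y, x); ``masks`` likewise.  Voxel
    values are moved, never interpolated, and the padding guarantees that no
    nonzero voxel is lost.  Returns ``(registered_timelapse, registered_masks)``.
    """
    any_stack = next(iter(timelapse.values()))
    nt = any_stack.shape[0]
    if offsets.n_frames != nt:
        raise ValueError("offsets length != number of frames")
    pad_before = offsets.padding[:, 0]
    padded = tuple(
        any_stack.shape[1 + ax] + offsets.padding[ax].sum() for ax in range(3)
    )

    def register_stack(stack):
        if stack.shape[1:] != any_stack.shape[1:]:
            raise ValueError("stack shape mismatch across inputs")
        return np.stack(
            [
                _shift_into(padded, stack[t], offsets.offsets[t], pad_before)
                for t in range(nt)
            ]
        )

    reg = {ch: register_stack(stack) for ch, stack in timelapse.items()}
    reg_masks = None
    if masks is not None:
        reg_masks = {name: register_stack(m) for name, m in masks.items()}
    return reg, reg_masks
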