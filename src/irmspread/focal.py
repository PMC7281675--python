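"""Focal activity maps and integrated tapping activity.

The focal activity map is the signed per-pixel difference of consecutive IRM
frames, ``delta[t] = frame[t] - frame[t+1]``.  Because darker means closer to
the substrate, a positive delta marks local *attachment* (the pixel got
darker between t and t+1) and a negative delta marks local *detachment*.

The integrated tapping activity condenses each difference image to a scalar:
the mean of ``|delta|`` over the platelet's bounding box — a per-frame
measure of total attachment/detachment flux.  Using the mean (not the sum)
makes the trace comparable across bounding boxes of different sizes, at the
cost of dilution by background pixels inside the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IRMSequence, PlateletROI, BackgroundROI

__all__ = [
    "FocalActivityMap",
    "ActivityTrace",
    "focal_activity_map",
    "integrated_tapping_activity",
    "bin_activity",
]


@dataclass(frozen=True)
class FocalActivityMap:
    """Signed (T-1, H, W) difference stack; positive = local attachment."""

    deltas: np.ndarray
    frame_interval: float = 5.0
    roi: PlateletROI | None = None

    def __post_init__(self):
        deltas = np.asarray(self.deltas)
        if deltas.ndim != 3 or deltas.shape[0] < 1:
            raise ValueError(f"deltas must be a non-empty (T-1, H, W) stack, "
                             f"got shape {deltas.shape}")
        object.__setattr__(self, "deltas", deltas)

    @property
    def n_steps(self) -> int:
        return self.deltas.shape[0]


@dataclass(frozen=True)
class ActivityTrace:
    """Per-frame mean |delta| over an ROI; length T-1, all values >= 0."""

    values: np.ndarray
    frame_interval: float = 5.0
    roi: PlateletROI | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(values < 0):
            raise ValueError("activity values must be non-negative")
        object.__setattr__(self, "values", values)


def focal_activity_map(seq: IRMSequence,
                       roi: PlateletROI | BackgroundROI | None = None
                       ) -> FocalActivityMap:
    """Compute ``delta[t] = frame[t] - frame[t+1]`` over an ROI crop.

    The ROI crop (bounding box and, for a :class:`PlateletROI`, its frame
    range) is applied before differencing so neighbouring platelets cannot
    leak into the map.  Differences are computed in float64 so unsigned
    integer input cannot wrap around.
    """
    frames = seq.frames
    platelet_roi = None
    if isinstance(roi, PlateletROI):
        roi.validate_against(seq)
        frames = roi.slice_frames(frames)
        platelet_roi = roi
    elif isinstance(roi, BackgroundROI):
        frames = roi.crop(frames)
    if frames.shape[0] < 2:
        raise ValueError(
            f"need at least 2 frames within the ROI frame range, "
            f"got {frames.shape[0]}")
    frames = frames.astype(np.float64, copy=False)
    deltas = frames[:-1] - frames[1:]
    return FocalActivityMap(deltas, frame_interval=seq.frame_interval,
                            roi=platelet_roi)


def integrated_tapping_activity(fam: FocalActivityMap) -> ActivityTrace:
    """Mean absolute delta per frame — the integrated tapping activity.

    Insensitive to any constant offset added to all frames (the offset
    cancels in the difference).
    """
    values = np.abs(fam.deltas).mean(axis=(1, 2))
    return ActivityTrace(values, frame_interval=fam.frame_interval, roi=fam.roi)


def bin_activity(fam: FocalActivityMap, bin_size: int = 3) -> FocalActivityMap:
    """Average the map over non-overlapping ``bin_size`` x ``bin_size`` blocks.

    Each block is replaced by its mean delta; ragged edge blocks are averaged
    over the pixels they actually contain.  ``bin_size=1`` is the identity.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    n, h, w = fam.deltas.shape
    if bin_size > h or bin_size > w:
        raise ValueError(f"bin_size {bin_size} larger than ROI ({h}x{w})")
    if bin_size == 1:
        return fam

    hb = -(-h // bin_size)
    wb = -(-w // bin_size)
    out = np.empty((n, hb, wb), dtype=np.float64)
    for i in range(hb):
        for j in range(wb):
            block = fam.deltas[:, i * bin_size:(i + 1) * bin_size,
                               j * bin_size:(j + 1) * bin_size]
            out[:, i, j] = block.mean(axis=(1, 2))
    return FocalActivityMap(out, frame_interval=fam.frame_interval, roi=fam.roi)
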