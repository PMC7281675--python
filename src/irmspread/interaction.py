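"""Surface-interaction segmentation by a pooled Otsu threshold.

All intensities of a platelet's cropped time-lapse are pooled into one
histogram and a single Otsu threshold is computed for the whole movie (never
per frame).  Pixels strictly below the threshold are "interacting with the
surface" (IRM foreground: darker = closer); pixels at or above it are not.
From the resulting boolean stack the module derives the interaction-area
curve and the accumulated interaction -> non-interaction transition map,
whose hot pixels mark unstable, repeatedly detaching contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import IRMSequence, PlateletROI

__all__ = [
    "DegenerateHistogramError",
    "InteractionMask",
    "TransitionMap",
    "OtsuInteractionSegmenter",
    "pooled_otsu_threshold",
    "interaction_mask",
    "interaction_area_trace",
    "accumulate_transitions",
]

#: float input (and integer input with a very wide range) is histogrammed
#: into this many equal-width bins before the between-class-variance search
N_BINS_FLOAT = 256
#: integer input keeps one bin per value up to this many bins
MAX_NATIVE_BINS = 65536


class DegenerateHistogramError(ValueError):
    """Raised when the pooled histogram has fewer than two distinct values."""


@dataclass(frozen=True)
class InteractionMask:
    """Boolean (T, H, W) stack over the ROI; True = interacting; plus the
    pooled Otsu threshold that produced it."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3 or mask.dtype != bool:
            raise ValueError("mask must be a boolean (T, H, W) stack")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class TransitionMap:
    """Per-pixel count of interaction -> non-interaction switches from frame 0
    up to a given frame."""

    counts: np.ndarray
    up_to_frame: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or np.any(counts < 0):
            raise ValueError("counts must be a non-negative (H, W) array")
        object.__setattr__(self, "counts", counts)


def _histogram_edges(values: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram counts and candidate thresholds for the pooled intensities.

    Integer data with a range of at most MAX_NATIVE_BINS keeps one bin per
    integer value; anything wider, and float data, uses N_BINS_FLOAT
    equal-width half-open bins over [min, max].  Candidate thresholds are the
    interior bin edges: classifying with threshold ``edges[j]`` puts bins
    0..j-1 (values < edges[j]) in the foreground class.
    """
    vmin = values.min()
    vmax = values.max()
    if np.issubdtype(values.dtype, np.integer) and \
            int(vmax) - int(vmin) + 1 <= MAX_NATIVE_BINS:
        n_bins = int(vmax) - int(vmin) + 1
        counts = np.bincount((values.astype(np.int64) - int(vmin)).ravel(),
                             minlength=n_bins)
        centers = np.arange(int(vmin), int(vmax) + 1, dtype=np.float64)
        edges = centers + 1.0  # threshold edges[j] puts values <= vmin+j below
        return counts.astype(np.float64), edges, centers
    n_bins = N_BINS_FLOAT
    counts, bin_edges = np.histogram(values.astype(np.float64).ravel(),
                                     bins=n_bins, range=(float(vmin), float(vmax)))
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    # values equal to vmax land in the last half-open bin by numpy convention
    return counts.astype(np.float64), bin_edges[1:], centers


def _otsu_from_histogram(counts: np.ndarray, edges: np.ndarray,
                         centers: np.ndarray) -> float:
    """Between-class-variance maximisation; ties broken by smallest threshold."""
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not np.any(valid):
        raise DegenerateHistogramError(
            "degenerate histogram: pooled intensities have a single class")
    mu0 = np.where(valid, csum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (tsum - csum) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(between))  # argmax takes the first = smallest edge
    return float(edges[best])


class OtsuInteractionSegmenter(BaseEstimator, TransformerMixin):
    """Label pixels "interacting with the surface" via one pooled Otsu threshold.

    ``fit`` pools every pixel intensity of the (optionally ROI-cropped)
    time-lapse into a single histogram and stores the Otsu threshold that
    maximises between-class variance.  ``transform`` applies that one
    threshold to every frame with a strict less-than comparison (pixels
    exactly at the threshold are background).

    Attributes
    ----------
    threshold_ : float
        The pooled Otsu threshold, within the pooled intensity range.
    n_pooled_ : int
        Number of intensities pooled during ``fit``.
    """

    def __init__(self, roi: PlateletROI | None = None):
        self.roi = roi

    def _frames(self, X) -> np.ndarray:
        frames = X.frames if isinstance(X, IRMSequence) else np.asarray(X)
        if frames.ndim != 3:
            raise ValueError(f"expected a (T, H, W) stack, got shape {frames.shape}")
        if self.roi is not None:
            if isinstance(X, IRMSequence):
                self.roi.validate_against(X)
            frames = self.roi.slice_frames(frames)
        return frames

    def fit(self, X, y=None):
        values = self._frames(X)
        if np.unique(values).size < 2:
            raise DegenerateHistogramError(
                "degenerate histogram: constant-intensity sequence")
        counts, edges, centers = _histogram_edges(values)
        self.threshold_ = _otsu_from_histogram(counts, edges, centers)
        self.n_pooled_ = int(values.size)
        return self

    def transform(self, X) -> InteractionMask:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("OtsuInteractionSegmenter is not fitted")
        frames = self._frames(X)
        return InteractionMask(mask=frames < self.threshold_,
                               threshold=self.threshold_)


# ---------------------------------------------------------------------------
# functional wrappers


def pooled_otsu_threshold(seq: IRMSequence, roi: PlateletROI | None = None) -> float:
    """Otsu threshold of all intensities pooled across the (cropped) movie."""
    return OtsuInteractionSegmenter(roi=roi).fit(seq).threshold_


def interaction_mask(seq: IRMSequence, roi: PlateletROI | None = None,
                     threshold: float | None = None) -> InteractionMask:
    """Boolean interaction labelling with one global threshold (strict ``<``).

    If *threshold* is None the pooled Otsu threshold is computed first.
    """
    if threshold is None:
        return OtsuInteractionSegmenter(roi=roi).fit(seq).transform(seq)
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    frames = seq.frames if roi is None else roi.slice_frames(seq.frames)
    return InteractionMask(mask=frames < threshold, threshold=float(threshold))


def interaction_area_trace(mask: InteractionMask) -> np.ndarray:
    """Number of interacting pixels at each frame (the spreading-area curve)."""
    return mask.mask.sum(axis=(1, 2)).astype(np.int64)


def accumulate_transitions(mask: InteractionMask, up_to_frame: int | None = None
                           ) -> TransitionMap:
    """Count interaction -> non-interaction switches per pixel from frame 0.

    ``counts[p]`` is the number of steps ``t < up_to_frame`` where the pixel
    was interacting at ``t`` and not at ``t+1``.  Only True -> False
    transitions are counted; the reverse count is derivable and not stored.
    """
    t_total = mask.mask.shape[0]
    if up_to_frame is None:
        up_to_frame = t_total - 1
    if not (0 <= up_to_frame < t_total):
        raise ValueError(f"up_to_frame {up_to_frame} outside [0, {t_total})")
    m = mask.mask[:up_to_frame + 1]
    drops = m[:-1] & ~m[1:]
    counts = drops.sum(axis=0).astype(np.int64)
    return TransitionMap(counts=counts, up_to_frame=up_to_frame)
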