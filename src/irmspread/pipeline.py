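"""Per-platelet analysis orchestration and trace-level detectors.

``analyze_platelet`` runs the full chain on one movie + annotation set:
focal activity map, integrated tapping activity, pooled-Otsu interaction
mask, interaction-area curve, accumulated transition map, background-model
calibration and attach/detach fractions, and bundles the per-frame series
into a tidy DataFrame ready for CSV export.

The detectors recover event structure from the interaction-area curve
alone:

* ``detect_attachment``      — first sustained crossing of a minimum area
  (the automatic surrogate for manually annotated attachment);
* ``detect_lamellipodia_onset`` — changepoint where the curve switches from
  fluctuating-flat (filopodial tapping) to sustained growth, found by a
  flat-then-line two-segment least-squares fit;
* ``estimate_tapping_period``   — dominant oscillation period of a region's
  area trace via the autocorrelation peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (BackgroundROI, IRMSequence, PhaseAnnotation, PlateletROI,
                 export_traces)
from .focal import FocalActivityMap, focal_activity_map, integrated_tapping_activity
from .interaction import (InteractionMask, OtsuInteractionSegmenter,
                          TransitionMap, accumulate_transitions,
                          interaction_area_trace)
from .events import (ActivePixelClassifier, EventLabels,
                     attach_detach_fractions, fit_background_model)

__all__ = [
    "PlateletAnalysis",
    "analyze_platelet",
    "detect_attachment",
    "detect_lamellipodia_onset",
    "estimate_tapping_period",
    "spreading_window",
]


@dataclass(frozen=True)
class PlateletAnalysis:
    """All per-platelet outputs of the quantification chain."""

    platelet_id: str
    frame_interval: float
    tapping_activity: np.ndarray        # length T-1
    interaction_area: np.ndarray        # length T
    attach_fraction: np.ndarray         # length T-1, NaN where no active pixels
    detach_fraction: np.ndarray
    mask: InteractionMask
    transition_map: TransitionMap
    labels: EventLabels
    fam: FocalActivityMap
    threshold: float
    background_mean: float
    background_sd: float

    def traces_frame(self) -> pd.DataFrame:
        """Per-frame series on a common time base (delta series padded with NaN
        at the last frame)."""
        t = len(self.interaction_area)
        pad = np.full(t, np.nan)
        pad[:t - 1] = self.tapping_activity
        att = np.full(t, np.nan)
        att[:t - 1] = self.attach_fraction
        det = np.full(t, np.nan)
        det[:t - 1] = self.detach_fraction
        return pd.DataFrame({
            "time_seconds": np.arange(t) * self.frame_interval,
            "tapping_activity": pad,
            "interaction_area": self.interaction_area.astype(np.float64),
            "attach_fraction": att,
            "detach_fraction": det,
        })

    def export_csv(self, path) -> None:
        df = self.traces_frame()
        export_traces({c: df[c].to_numpy() for c in df.columns if c != "time_seconds"},
                      path, frame_interval=self.frame_interval)


def analyze_platelet(seq: IRMSequence, roi: PlateletROI, bg: BackgroundROI,
                     *, k: float = 1.0,
                     fractions_denominator: str = "active") -> PlateletAnalysis:
    """Run the full single-platelet quantification chain."""
    roi.validate_against(seq)
    fam = focal_activity_map(seq, roi)
    activity = integrated_tapping_activity(fam)

    seg = OtsuInteractionSegmenter(roi=roi).fit(seq)
    mask = seg.transform(seq)
    area = interaction_area_trace(mask)
    transitions = accumulate_transitions(mask)

    bg_fam = focal_activity_map(seq, bg)
    clf = ActivePixelClassifier(k=k).fit(bg_fam)
    labels = clf.predict(fam)
    attach, detach = attach_detach_fractions(labels,
                                             denominator=fractions_denominator)

    return PlateletAnalysis(
        platelet_id=roi.platelet_id,
        frame_interval=seq.frame_interval,
        tapping_activity=activity.values,
        interaction_area=area,
        attach_fraction=attach,
        detach_fraction=detach,
        mask=mask,
        transition_map=transitions,
        labels=labels,
        fam=fam,
        threshold=seg.threshold_,
        background_mean=clf.mean_,
        background_sd=clf.sd_,
    )


def detect_attachment(area: np.ndarray, *, min_pixels: int = 20,
                      consecutive: int = 3) -> int | None:
    """First frame where the interaction area reaches ``min_pixels`` for
    ``consecutive`` frames in a row; None if it never does.

    This is the automatic surrogate for a manually annotated
    onset-of-immobilization time point.
    """
    area = np.asarray(area)
    ok = area >= min_pixels
    run = 0
    for t, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= consecutive:
            return t - consecutive + 1
    return None


def detect_lamellipodia_onset(area: np.ndarray, *,
                              activity_threshold: float = 1.0,
                              plateau_quantile: float = 0.9) -> int | None:
    """Changepoint where the area curve switches from fluctuating-flat to
    sustained growth — the filopodia-to-lamellipodia transition.

    The filopodial stage produces an area trace oscillating about a constant
    mean; lamellipodial growth produces a monotone rise to a plateau.  The
    detector fits, for every candidate breakpoint, a constant segment
    followed by an unconstrained straight line over the window from the
    first activity to the point where the curve reaches
    ``plateau_quantile`` of its maximum, and returns the breakpoint with the
    smallest summed squared error.  Returns None when the curve never grows
    (an arrested or background movie).
    """
    area = np.asarray(area, dtype=np.float64)
    n = len(area)
    if n < 5:
        return None
    active = np.flatnonzero(area > activity_threshold)
    if active.size == 0:
        return None
    t_start = int(active[0])
    peak = area.max()
    fil_scale = np.quantile(area[t_start:], 0.25)
    if peak < max(4.0 * max(fil_scale, 1.0), 10.0):
        return None  # never grew beyond filopodial fluctuation scale
    t_end = int(np.argmax(area >= plateau_quantile * peak))
    if t_end - t_start < 4:
        return None

    window = area[t_start:t_end + 1]
    m = len(window)
    x = np.arange(m, dtype=np.float64)
    best_tau, best_sse = None, np.inf
    for tau in range(1, m - 1):
        seg1 = window[:tau]
        sse1 = float(((seg1 - seg1.mean()) ** 2).sum())
        seg2 = window[tau:]
        x2 = x[tau:]
        coef = np.polyfit(x2, seg2, 1)
        sse2 = float(((seg2 - np.polyval(coef, x2)) ** 2).sum())
        if sse1 + sse2 < best_sse:
            best_sse, best_tau = sse1 + sse2, tau
    if best_tau is None:
        return None

    # the straight-line segment under-reaches convex early growth, biasing
    # the breakpoint late; refine to the first point after which the curve
    # permanently leaves the flat segment's fluctuation band
    flat = window[:max(best_tau - 2, 2)]
    band = flat.mean() + 3.0 * flat.std()
    suffix_min = np.minimum.accumulate(window[::-1])[::-1]
    above = np.flatnonzero(suffix_min > band)
    if above.size:
        return t_start + int(above[0])
    return t_start + best_tau


def spreading_window(area: np.ndarray, *, area_quantile: float = 0.95
                     ) -> tuple[int, int] | None:
    """Frame range [onset, end) of active lamellipodial spreading.

    Starts at the detected filopodia-to-lamellipodia changepoint and ends
    when the area first reaches ``area_quantile`` of its final value —
    i.e. the frames during which the contact area is actually growing.
    None when no lamellipodial growth is detected.
    """
    area = np.asarray(area, dtype=np.float64)
    onset = detect_lamellipodia_onset(area)
    if onset is None:
        return None
    end = int(np.argmax(area >= area_quantile * area.max()))
    if end <= onset:
        return None
    return onset, end


def estimate_tapping_period(trace: np.ndarray, frame_interval: float = 1.0,
                            *, max_lag: int | None = None,
                            peak_threshold: float = 0.25) -> float | None:
    """Dominant oscillation period (seconds) via the autocorrelation peak.

    The trace is mean-centred and its autocorrelation peaks at every multiple
    of the period.  A non-integer period aligns better with some multiples
    than others on the integer lag grid, so picking the single highest peak
    can land on a harmonic; instead the period is the median spacing between
    successive peaks (local maxima reaching ``peak_threshold`` of the
    highest one), which stays on the fundamental.  Returns None for flat
    traces or when no interior peak exists.
    """
    x = np.asarray(trace, dtype=np.float64)
    n = len(x)
    if n < 6:
        return None
    x = x - x.mean()
    if not np.any(x):
        return None
    ac = np.correlate(x, x, mode="full")[n - 1:]
    ac = ac / ac[0]
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 2)
    peaks = [lag for lag in range(2, max_lag)
             if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1]]
    if not peaks:
        return None
    best_val = max(ac[lag] for lag in peaks)
    kept = [lag for lag in peaks if ac[lag] >= peak_threshold * best_val]
    if len(kept) == 1:
        return kept[0] * frame_interval
    return float(np.median(np.diff(kept))) * frame_interval
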