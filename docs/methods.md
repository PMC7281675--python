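# Methods

## Measurement model

IRM contrast is treated as a monotone proxy for membrane–substrate
distance: darker pixels are closer. No interference (fringe) physics is
modelled or assumed anywhere; every statistic below consumes only the
ordering "darker = closer" and the raw intensity values. Intensities are
kept in native camera units end to end — the pooled Otsu threshold and the
background-SD event thresholds both act on raw values, so any rescaling on
load would silently change results. Coordinates are 0-based and half-open;
time in seconds is always `frame_index * frame_interval` (non-uniform
intervals are rejected, not interpolated).

## Per-platelet statistics

**Focal activity map.** `delta[t] = frame[t] − frame[t+1]` on the
ROI-cropped stack (cropping first keeps neighbouring cells out of the
trace). Differences are taken in float64 so unsigned integer input cannot
wrap. Positive = local attachment, negative = local detachment. The map is
antisymmetric under time reversal, invariant to constant intensity offsets,
and telescopes to `frame[0] − frame[T−1]`; all three are tested.

**Integrated tapping activity.** The mean of |delta| over the bounding box
per frame. The mean (not the sum) is used so traces are comparable across
box sizes; the price is that empty background pixels inside the box dilute
the magnitude, which is why the trace is a relative, per-platelet measure.
Activity maps can additionally be averaged over non-overlapping
`bin_size`×`bin_size` blocks (default 3) for coarse-grained display; ragged
edge blocks average over the pixels they actually contain.

**Surface-interaction segmentation.** All intensities of the cropped movie
are pooled into one histogram and a single Otsu threshold (maximum
between-class variance) is computed for the whole sequence — never per
frame, so the labelling is consistent in time. Integer data keeps one bin
per value (up to 16-bit range); float data, or wider ranges, use 256
equal-width half-open bins over [min, max]. Candidate thresholds are the
interior bin edges; the comparison is a strict `intensity < threshold`
(pixels exactly at the threshold are background) and ties in the variance
maximisation resolve to the smallest threshold. A constant-intensity movie
raises an explicit degenerate-histogram error rather than returning an
arbitrary cut. The implementation is validated against exhaustive search
over all candidate thresholds and cross-checked against scikit-image's
Otsu to within one histogram bin.

**Transition map.** For each pixel, the number of interaction →
non-interaction switches (`mask[t] ∧ ¬mask[t+1]`) accumulated from frame 0.
Only that direction is counted — the opposite count differs by at most one
and is derivable. Counts are cumulative-monotone in the upper frame bound.

**Event classification.** ΔIRM values of a manually marked empty background
box, pooled over all frames, give a null mean and SD (population divisor
n; with pools of thousands of values the n vs n−1 choice is immaterial but
must be fixed). Pixels with delta strictly above mean + k·SD are attaching,
strictly below mean − k·SD detaching; k defaults to 1. On pure Gaussian
noise, calibrating on the same distribution that is classified makes the
active fraction exactly 2·Φ(−1) ≈ 0.3173 in expectation — the control
property the classifier is tested against. Attach/detach fractions are
computed over active pixels (so they are complementary); frames with no
active pixel yield NaN, never 0/0. A per-ROI-pixel normalisation is
available behind `denominator="roi"` but is not the default.

## Trace-level detectors

**Attachment surrogate.** Where no manual onset-of-immobilization
annotation exists, attachment is the first frame at which the interaction
area reaches 20 px for 3 consecutive frames. This is an operational
surrogate for a manual call and is labelled as such.

**Lamellipodia-onset changepoint.** The filopodial stage produces an area
trace oscillating about a constant mean; lamellipodial growth produces a
monotone rise. The detector fits, for each candidate breakpoint, a constant
segment followed by a free straight line over the window from first
activity to the 90%-of-max crossing and takes the minimum-SSE breakpoint.
Because a straight line under-reaches convex early growth, the raw
breakpoint is biased late by a few frames; it is refined to the first frame
after which the curve permanently exceeds the flat segment's mean + 3 SD
band. Arrested and background movies (no growth beyond ~4× the filopodial
fluctuation scale) return no onset.

**Tapping-period estimator.** The autocorrelation of a mean-centred
region-area trace peaks at every multiple of the oscillation period. A
non-integer period (e.g. 5.5 s sampled at 1 s) aligns better with some
multiples than others on the integer lag grid, so taking the single highest
peak occasionally lands on a harmonic; instead the period is the median
spacing between successive prominent peaks (local maxima reaching 25% of
the highest), which stays on the fundamental. Validated to <1 frame error
over 240 simulated filopodia.

**Spreading window.** "Frames during which the platelet is spreading" are
defined as the detected onset up to the 95%-of-final-area crossing. The
logistic radius saturates before the annotated plateau onset; after growth
stops, attach and detach counts are symmetric noise, so including those
frames would measure noise rather than spreading.

## Cohort statistics

Attachment curves are scaled empirical CDFs (percent attached by time t;
censored platelets never count). Phase durations are onset differences
times the frame interval; absent stages give absent durations, never zero.
Endpoint fractions are plain class frequencies over
{no_attach, filopodial, fully_spread}, reported with group n.

The Wilcoxon rank-sum test reports the rank-sum of the first sample
(midranks under ties) and a two-sided p. For pooled n ≤ 12 the p-value is
computed by full enumeration of rank assignments — exact under the
permutation null even with ties, and giving p = 1 exactly for identical
samples. Larger samples use the normal approximation with tie and
continuity correction. At the pooled-n = 12 boundary the two-sided gap
between branches is bounded by ~0.02 over the balanced 6+6 lattice (the
doubling rule doubles the per-tail discretisation error of ~half a lattice
step); this is an intrinsic property of the normal approximation at that
size, not an implementation artefact.

## Synthetic movies

The generator emulates the statistical structure the analysis assumes, with
full ground truth (per-pixel contact states, phase onsets, per-filopodium
tapping periods, final area). Default conditions:

| parameter | default | why |
|---|---|---|
| frame interval | 1 s | resolves 5–10 s tapping; `decimate_sequence` emulates 5 s acquisition and its aliasing |
| phases (hover/filopodial/lamellipodial/plateau) | 20/60/60/40 s | a compressed but ordered version of the observed phase script |
| tapping period | uniform [5, 10] s per filopodium | the observed oscillation band; square wave, 50% duty |
| filopodia | 6 radial segments, 10×1 px, appearing one by one over the first half of the filopodial phase | staggered appearance makes total tapping activity build to a peak as the stage completes |
| contact darkening | 40 units below a background of 100 | comfortably detectable above the noise |
| pixel noise | Gaussian, SD 2 | no camera statistics are available; all recovery tolerances are stated relative to this choice |
| hover blob | Gaussian bump, +3 units (1.5× noise SD) | strictly brighter than background, so pre-attachment frames contribute no interaction pixels by construction |
| lamellipodial growth | logistic radius, r0 = 3 px → R = 20 px, g = 0.15 s⁻¹ | monotone growth to a plateau within the phase |
| adhesion maturation | new disk pixels start at 60% darkening, full after 5 s | see below |
| contact jitter | SD 2 on touching pixels | residual membrane-height fluctuation; keeps the spread footprint more active than empty glass |

Two features extend a strictly two-level (touching/not) contrast model:
**adhesion maturation** of lamellipodial pixels and **contact jitter**.
Without them a binary-contrast movie would show an attach/detach-balanced
spread plateau at exactly the background activity level and an advancing
front contributing a single attach event per pixel — and the qualitative
signatures the analysis is meant to detect (attachment-dominated spreading,
plateau activity above the pre-attachment baseline) would not exist in the
data. Transient tapping contacts do not mature, which preserves the
attach/detach symmetry of the fibrinogen-like cycling scenario. Setting
`immature_darkening_fraction=1.0, contact_jitter_sd=0` recovers the pure
two-level model; the monotone-growth transition-map tests use it.

Presets: `collagen_like` runs the full phase script; `fibrinogen_like`
prolongs whole-filopodium cycling and, with probability 0.57, never starts
the lamellipodial phase (arrest); `background_only` is pixel noise only.
The synthetic cohort generator draws exponential attachment times with
median 60 s (collagen-like) vs 120 s (fibrinogen-like), censored at 3600 s
— the speed ratio is a chosen, realistic 2×, not a fitted value.

Determinism: all draws derive from one seed in a fixed order, so identical
configs give bit-identical movies.

## What the simulations do and do not show

Passing recovery tests shows the pipeline measures what it claims on data
whose ground truth is known and whose contrast, noise and phase structure
match its assumptions. Real IRM movies additionally contain interference
fringes, uneven illumination, focus drift, neighbouring cells and
motion — none of which are simulated, and no flat-field or drift correction
is included. Recovery on synthetic data is therefore a correctness check of
the computation, not a validation of robustness to those artefacts.

## Problem sizes

Default test and reproduction sizes: 64×64 px movies, 180 frames at 1 s; 20
simulated platelets per recovery batch; 200 replicate cohorts of 274 + 121
platelets for the rank-sum power re-enactment; 100 random stacks for the
Otsu oracle; 1000 random pixel histories for the transition oracle. These
sizes give tight, reproducible statistics while keeping a full run in the
order of seconds.
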