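# irmspread

Quantification of single-platelet adhesion dynamics from interference
reflection microscopy (IRM) time-lapse movies.

In IRM, the reflected-light intensity of a pixel reports how close the cell
membrane is to the glass: **darker = closer**. A spreading platelet imaged
this way goes through a stereotyped sequence — a bright out-of-focus blob
while it hovers above the surface, thin filopodia that "tap" the substrate
with a ~5–10 s attach/detach oscillation, then a lamellipodial sheet that
grows a dark contact footprint to a plateau. `irmspread` turns such movies
into numbers:

* **Focal activity map** — the signed frame difference
  ΔIRM<sub>t</sub> = IRM<sub>t</sub> − IRM<sub>t+1</sub>; positive values are
  local attachment (the next frame is darker/closer), negative values local
  detachment.
* **Integrated tapping activity** — mean |ΔIRM| over the platelet's bounding
  box per frame: a scalar trace of total attach/detach flux.
* **Surface-interaction mask** — all intensities of a movie are pooled into
  one histogram; a single Otsu threshold labels every pixel at every frame
  as interacting (below threshold) or not. From it: the interaction-area
  curve and the per-pixel count of interaction → non-interaction
  transitions, which highlights unstable peripheral contacts.
* **Attach/detach event classification** — ΔIRM values of an empty
  background region calibrate mean μ and SD σ; pixels with
  ΔIRM > μ + kσ are attaching, ΔIRM < μ − kσ detaching (k = 1 by default),
  and the per-frame attach fraction is |attach| / (|attach| + |detach|).
* **Cohort kinetics** — attachment-percentage curves (scaled empirical
  CDFs), phase durations from stage annotations, endpoint-class fractions,
  and the two-sided Wilcoxon rank-sum test (exact by enumeration for pooled
  n ≤ 12, tie- and continuity-corrected normal approximation beyond).
* **Synthetic movie generator** — IRM-like spreading movies with full
  ground truth (per-pixel contact states, phase onsets, tapping periods),
  so every stage of the pipeline is validated by recovery, not by eye.

The two genuinely model-like stages follow the scikit-learn estimator API:
`OtsuInteractionSegmenter` (fit pools intensities → `threshold_`; transform
→ mask) and `ActivePixelClassifier` (fit background ΔIRM pool → `mean_`,
`sd_`; predict → event labels).

## Worked example

```python
from irmspread import scenario_preset, simulate_movie, analyze_platelet
from irmspread.pipeline import detect_lamellipodia_onset, estimate_tapping_period

cfg = scenario_preset("collagen_like", seed=42)
seq, truth, roi, bg, ann = simulate_movie(cfg)
result = analyze_platelet(seq, roi, bg)

onset = detect_lamellipodia_onset(result.interaction_area)
print(f"pooled Otsu threshold: {result.threshold:.2f}")
print(f"detected lamellipodia onset: frame {onset} (truth: {truth.lamellipodia_onset})")
print(f"final interaction area: {result.interaction_area[-1]} px (truth: {truth.final_area})")
```

prints

```
pooled Otsu threshold: 80.45
detected lamellipodia onset: frame 81 (truth: 80)
final interaction area: 1245 px (truth: 1245)
```

The threshold sits between the contact mode (~60 intensity units) and the
background mode (~100); the filopodia-to-lamellipodia switch is recovered
within a frame from the interaction-area curve's growth changepoint; the
final footprint is recovered exactly. Restricting the mask to one
filopodium's footprint and autocorrelating its area trace recovers that
filopodium's tapping period (here 9.0 s against a ground truth of 8.87 s).

The same chain is available from the shell:

```sh
irmspread simulate --preset collagen_like --seed 42 --out-dir sim/
irmspread analyze sim/movie.tif sim/annotations.csv --frame-interval 1 --out-dir out/
irmspread cohort cohort.csv --out-dir summary/
```

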