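# Methods

## Problem

Real-time cardiac MRI (~30 frames/s) images the thorax continuously during
free breathing, while MR-compatible spirometry (125 Hz) measures airflow at
the mouth. After a short learning phase in which both are recorded
together, the image stream alone carries enough information to recover
quantitative airflow and — by integration — lung volume for the rest of the
examination. `respiro` implements that predictor, the training-protocol
reduction experiments around it, the evaluation statistics, and a synthetic
breathing phantom on which everything is testable end to end.

## Model

Per slice, each pair of consecutive frames is reduced to an optical-flow
tensor and regressed against spirometry:

1. **ROI mask.** A binary mask restricts analysis to breathing-affected
   pixels. Real masks are drawn by a reader; `mask_from_motion` derives a
   stand-in by thresholding the temporal standard-deviation image at its
   q-th percentile (default q = 75).
2. **Downsampling.** Masked 200×200 frames are reduced to 40×40 by exact
   block means (an anti-aliased resize covers non-divisible geometries).
3. **Iterative Lucas-Kanade.** Ten warp iterations of windowed
   least-squares optical flow (window radius 7 on the 40×40 grid, single
   scale) yield X(l) ∈ R^{40×40×2}, the displacement field between frames
   l−1 and l. X(0) := 0 keeps one tensor per frame. Each iteration
   re-solves the *total* flow from gradients of the warped moving image
   (the error term is ∇I·d + ref − warped); this formulation, the one used
   by scikit-image's iLK solver, does not accumulate drift in weakly
   conditioned windows, where an incremental accumulator does. Locally
   singular 2×2 systems yield zero flow, so constant (e.g. fully masked)
   regions are exactly static.
4. **Linear predictor.** Airflow is z-scored with training statistics
   (μ_f, σ_f; population SD) and modeled as
   f̂_norm(l) = Σ_{mnk} W_mnk X_mnk(l) + b.
5. **Ridge fit.** W minimizes Σ_l (f̂_norm − f_norm)² + λ‖W‖², with the
   intercept unpenalized (features and target are centered; the system is
   solved in the kernel dual, O(L³) for L training frames rather than the
   3200-dimensional primal). λ is selected by exact leave-one-out
   cross-validation using the linear-smoother identity
   e_i^{(−i)} = e_i / (1 − H_ii), H_ii = 1/n + [K(K+λI)^{-1}]_ii, over a
   default grid of 13 penalties log-spaced in [10⁻³, 10³]; ties resolve to
   the larger λ. Leave-one-out is per frame; breath-wise CV is not
   implemented.
6. **Post-processing.** Predictions are denormalized (σ_f f̂_norm + μ_f),
   Savitzky-Golay smoothed (window 15 frames ≈ 0.5 s, polynomial order 3 —
   parameters are package defaults, exposed in `SmootherConfig`), and
   integrated to volume as v(t) = c Σ_{k≤t} f(k) with c = 10, the
   conventional magnitude constant. With 33 ms frames the physically exact
   scale would be frame_period·1000 ≈ 33 mL per unit flow (`physical_c`);
   since measured and predicted volumes share whichever constant is used,
   all relative/agreement statistics are unaffected. A baseline correction
   then removes drift accumulated from small flow biases:
   `linear_detrend` (default) subtracts the least-squares line;
   `breath_anchor` subtracts a line fitted through detected end-expiratory
   troughs; `none` disables it. Measured volumes are always integrated and
   corrected identically to predictions.

## Evaluation

rMSE (mean squared error over mean squared signal), R², and per-breath
statistics on breaths segmented at negative-to-positive zero crossings of
the lightly smoothed *measured* flow (segments shorter than 1 s merged):
aTVD = |TV_measured − TV_predicted| with TV the peak-to-trough range, and
aMFD = |max f − max f̂|. Bland-Altman bias and 1.96·SD limits of agreement
(sample SD) summarize one randomly selected breath pair per slice, seeded.
Quality criteria: QC_volume passes iff mean aTVD < 20 mL; QC_flow is
reported strict (≤ 50 mL/s) and lenient (≤ 100 mL/s), the lenient level
being the gate. Weight maps export √(W²_mn1 + W²_mn2) per pixel.

## Protocols

A protocol fixes per slice a 300-frame training block and the following
600-frame test block (test data identical across variants; training never
exceeds one third of acquired frames). Breath budgets thin the block to
whole breaths (4 deep + 4 normal … 1 normal, or a single inspiratory limb);
slice strides 1/2/3/6 train every k-th slice, untrained slices being
predicted by the nearest trained neighbour's model and mask (ties toward
the basal side). Cross-subject transfer pools index-matched slices of other
subjects (union of their motion masks) and can rigidly rotate the test
frames onto the training orientation before optical flow; an experimental
adaptive-denormalization mode substitutes NormStats estimated from a short
spirometry snippet of the test subject. Test-retest reuses scan-1 models
(two breaths, every second slice) on an independently acquired scan 2.

## Synthetic phantom

Each subject is a 2-D short-axis "thorax" per slice: an elliptical torso
with a bright chest wall band, a static mediastinal blob, and a bright
diaphragm dome whose vertical position moves linearly with instantaneous
lung volume; the chest wall expands radially, also linearly. Gains vary by
slice (basal diaphragm gain 30 mm/L tapering to 35 % apically, chest gain
growing apically) so adjacent-slice transfer is imperfect, as in a real
stack. Airflow is built from per-breath sinusoidal lobes whose inspiratory
half integrates exactly to the tidal volume, so tidal cycles close.
Defaults mirror the imaging world the method targets: 200×200 px at 33 ms,
19 slices × 900 frames acquired sequentially on a shared clock, spirometry
at 125 Hz, Gaussian intensity noise SD 0.02 on tissue plateaus in
[0.3, 1.0] (clipped after noise). Tidal breathing runs at 3.0 s per breath
(20 breaths/min, upper-normal at rest) with ±5 % uniform jitter on
amplitude and period — bounded jitter guarantees that a 9.9 s training
block always contains two whole breaths. Subject anatomy jitters ±5 %.

What the phantom does *not* emulate: MR physics (k-space, coils, banding),
cardiac motion, through-plane motion, breathing hysteresis, or any
nonlinearity between motion and volume. A green end-to-end test therefore
establishes that the estimator recovers a linear motion–volume world at
realistic noise, not that it handles real-thorax physiology. Two
consequences are documented and deliberate. First, because phantom motion
is linear in volume, a model trained on a single inspiratory limb
extrapolates sign-symmetrically and *does* predict negative airflow during
expiration, unlike the real-data observation that such training misses
negative flow; the companion effect (under-reached volume peaks) does
reproduce. Second, the analytic anatomy is close to rotationally
symmetric, and the windowed flow estimate is spatially smooth, so a 20°
orientation mismatch in cross-subject transfer costs only ~0.06–0.12 of
flow R² depending on the anatomy draw — qualitatively the right direction
(and rotation realignment recovers it essentially completely), but milder
than the severe degradation seen on real thoraces.

## Numerical choices

- Frame intervals are half-open [t, t+Δ); spirometry samples are averaged
  within each frame interval (linear, anti-aliasing).
- Population SD (ddof 0) in flow normalization; sample SD (ddof 1) in
  Bland-Altman limits.
- Optical-flow singular-system threshold |det| < 10⁻¹⁴ (images are O(1));
  bilinear warping; gradients by central differences.
- LOOCV leverage guard: any 1 − H_ii < 10⁻¹⁰ raises an ill-posed-fold
  error.
- σ_f below 10⁻¹² (relative) is treated as a degenerate constant signal.
- Determinism: every stochastic element (phantom anatomy, pixel noise,
  per-slice Bland-Altman pair selection, cohort subject parameters) derives
  from explicit seeds via seed sequences; identical configs give
  bit-identical scenes.

## Known limitations

- Single-scale optical flow: displacements beyond ~1 px/frame at the
  40×40 grid (violent motion) would need the pyramidal variant, which is
  out of scope.
- Breath segmentation assumes a usable spirometry ground truth; it is not
  a free-running respiratory gating method.
- Cross-subject slice matching is by index, not anatomical level.
- The adaptive-denormalization mode is an interpretation (training-shape
  weights with test-subject scale statistics) and is flagged experimental.
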