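# Methods

This note documents the models and procedures implemented in `strokesym`,
the assumptions behind them, the design choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real data.

## Problem setting

The package screens adolescent (12–17 y) table-tennis strokes for
left–right postural asymmetry and stratifies biomechanical injury risk.
Inputs are sequences of 17 keypoints per frame in the COCO convention
(default 30 frames per stroke at 60 Hz), either 2-D image coordinates or
3-D world coordinates. Risk here is *screening-sense* vulnerability —
rule-based exceedance of clinical thresholds — not a forecast of injury
incidence.

## Coordinate conventions

`image2d`: origin top-left, y increases downward, physical height is −y.
`world3d`: y-up, right-handed, coordinates in length units (the generator
uses metres). All angles are degrees. Mirroring reflects about the frame
vertical midline (image) or the x = 0 plane (world) and swaps left/right
joint labels; every indicator is an absolute difference or unsigned
angle, so indicator magnitudes and both rule labels are mirror-invariant
(property-tested).

## Asymmetry indicators

Per frame, six quantities:

1. **Shoulder rotation difference** `Δθ = |θ_r − θ_l|`. The per-side
   rotation is not uniquely defined by a keypoint skeleton; we use the
   elevation of the upper-arm vector out of the torso frontal plane (the
   plane spanned by the shoulder axis and the mid-hip→mid-shoulder axis)
   in 3-D, and the angle between the upper arm and the downward torso
   axis in 2-D. Both are unsigned, in [0°, 90°].
2. **Shoulder height difference** `Δh = |y_r − y_l| / H_body`,
   dimensionless, so the unresolved question of pixel- vs
   normalized-space heights is moot.
3. **Spinal lateral flexion** `α`. A quadratic `e(s) = a s² + b s + c` is
   interpolated through the cervical (shoulder midpoint), thoracic and
   lumbar (hip midpoint) landmarks in the spine-aligned frame: abscissa
   along the cervical–lumbar chord, ordinate the lateral deviation (the
   shoulder-axis component orthogonal to the chord). Fitting e(s) in this
   frame is well-conditioned for near-vertical spines, unlike fitting
   y(x) in world axes. The angle is `arctan(2a·x_vertex)`, computed via
   the algebraically identical `arctan(−b)`, which stays defined for
   collinear landmarks (a = 0). COCO-17 has no spine joints: the thoracic
   landmark is pluggable, defaulting to the torso midpoint. **Limitation:**
   the default proxy is collinear with the chord, so α degenerates to 0;
   meaningful spinal flexion requires a real thoracic estimate (the
   synthetic generator supplies the true landmark; pose estimators with a
   mid-spine joint can plug theirs in).
4. **Trunk rotation**: unsigned angle between the shoulder axis and hip
   axis after projection onto the transverse plane (3-D) or in the image
   plane (2-D), in [0°, 90°]. No closed-form reference definition exists
   for this quantity from keypoints; this is the package's choice.
5. **Hip flexion difference** `|θ_r − θ_l|` with per-side flexion = 180°
   minus the angle between hip→ipsilateral-shoulder and hip→knee (0° when
   standing straight).
6. **Pelvic obliquity** `γ = arctan((h_r − h_l)/d_hip)` with `d_hip` the
   Euclidean distance between the hip joints; signed, thresholded on
   magnitude.

**Kinematic descriptor.** A 5-frame sliding window yields 12 features:
the six indicators averaged over the window plus their first temporal
derivatives (end-to-end difference across the window divided by the
window duration, units per second). A 30-frame clip gives 26 windows.
The count of six indicators + six derivatives realizes the 12-feature
biomechanical vector; the constituent list is the package's choice.

## Threshold rules and labels

Adolescent operating defaults: shoulder 15° (rotation) or 0.05 (height
ratio), trunk 8° (spinal flexion magnitude), hip 10° (flexion difference)
or 5° (pelvic obliquity magnitude). All comparisons are strict
inequalities; boundary values do not fire (verified by bisection to
1e−10). Adult reference values are exposed as `value/(1 − r)` with
r = 12.5 % by default (the midpoint of the documented 10–15 % tightening).

* **Asymmetry label** (4-class): a segment fires if any of its indicators
  exceeds its threshold; with several firing segments the label is the
  one with the largest threshold-relative excess `(value − t)/t`. This
  single-label compression is lossy by design — multi-segment information
  lives in the risk level.
* **Risk level** (3-class): low = no segment exceeds, medium = exactly
  one, high = two or more simultaneously (within the same window, which
  operationalizes "co-occurring compensatory involvement" in a computable
  way).
* **Per-sample labels** are majority votes over the per-window labels,
  ties resolved toward the more severe class.

Age normalization `z = (θ − μ_age)/σ_age` is supported against per-year
(12–17) norm tables; σ must be positive, missing entries raise.

## 2-D → 3-D lifting

A deterministic anthropometric reconstruction for 2-D inputs: after
confidence-gated linear interpolation of missing joints (< 0.3
confidence, at most 30 % of frames per joint), each limb segment's depth
increment is the Pythagorean complement of its image-plane length
against the expected segment length (ratio × stature; torso 0.300,
upper arm 0.172, forearm 0.157, thigh 0.245, shank 0.246 — adolescent-
adjusted standard anthropometry), oriented toward the camera, rooted at
the hip plane, followed by a 3-frame moving average over time. The 2-D
projection of the output reproduces the input exactly. This is a
coarse, deliberately simple prior — it cannot disambiguate limbs bent
away from the camera — and is not used by the synthetic pipeline, which
generates 3-D data directly.

## Synthetic stroke generator

The generator is the package's test bed, replacing an access-restricted
video corpus. Design goals, in order: (1) injected asymmetry magnitudes
must be *exactly* recoverable by the indicator chain on noise-free data;
(2) labels must be rule-consistent by construction; (3) everything is
deterministic given a seed.

* **Templates.** Four stroke types (forehand drive, backhand push,
  serve, chop) as smooth sinusoid compositions of trunk rotation, arm
  elevation and hip flexion, peaking at the contact phase (0.7 of the
  clip ≈ the contact instant of a half-second stroke). The base motion
  is bilaterally symmetric, so all difference indicators vanish at zero
  asymmetry; a real stroke is of course one-armed — this is a deliberate
  trade of realism for testability, and means classifier performance on
  synthetic cohorts does not certify performance on real strokes. Base
  arm elevation stays below 45° so injected rotation offsets up to 44°
  remain in the measurable range of the frontal-plane elevation angle.
* **Injection.** Each of the five injectable asymmetries (shoulder
  rotation/height, spinal flexion, hip flexion, pelvic tilt) is an
  additive offset applied in the exact geometric frame the measurement
  inverts: arms are placed by rotating out of the measured frontal
  plane, the thoracic bow satisfies `e_t = −tan(α)·s_c/4`, and the hip
  height offset satisfies `Δh = w·tanγ/√(1 − tan²γ)` so the
  `arctan(Δh/d_hip)` measurement returns γ despite `d_hip` lengthening.
  Offsets follow a smooth envelope rising from phase 0.1 to a plateau
  from phase 0.45 through the end, which covers the contact frame (so
  the contact-window value equals the requested magnitude) and keeps a
  majority of windows above threshold for exceeding samples (so the
  majority-vote label matches the drawn label).
* **Cohorts.** Risk labels are drawn first from the study proportions
  (low/medium/high = 62.8/30.5/6.7 %, the ~1:15 high:low imbalance);
  the exceeding segments are then drawn from the asymmetry-class
  proportions renormalized over shoulder/trunk/hip, and magnitudes from
  label-conditional ranges (sub-threshold ≤ 0.6×t for quiet segments,
  1.3–2.2×t for exceeding ones). Under the rule labeler "normal" and
  "low risk" coincide, so the normal-class marginal equals the low-risk
  marginal by construction; the two printed marginals cannot both hold
  for rule-consistent labels, and risk was chosen as authoritative
  because the risk rules are the quantitatively specified ones. Ages are
  uniform over 12–17, stature is age-dependent Gaussian (1.50 m + 4 cm/y,
  σ = 7 cm), 85 % right-handed. Observation noise is isotropic Gaussian
  (σ = 0.01 body heights by default); labels always come from the
  noise-free trajectory.
* **Appearance features.** The "RGB" modality is a deterministic
  16×16 stick-figure occupancy grid per frame, flattened to 256 values —
  real pose information without pixels or pretrained networks. It is a
  synthetic stand-in by design, not an HRNet replacement.

## Network

Data flow: per-modality summaries → cross-modal attention → 512-d fused
vector → broadcast-concatenation onto per-joint embeddings → 3-layer GCN
→ joint pooling → 4-layer causal dilated TCN → temporal mean pooling →
shared trunk (BatchNorm + dropout 0.5) → two heads (→128→64→{4,3}).

* **Graph.** `H' = σ(D̃^{−1/2}ÃD̃^{−1/2} H W)` with Ã the weighted
  adjacency plus self-connections; the racket-arm chain (shoulder–elbow,
  elbow–wrist, shoulder–hip on the racket side) carries weight 1.5 and
  the two diagonal shoulder↔opposite-hip edges 1.3. Per-sample
  handedness selects the mirrored adjacency. Self-connections are added
  only at normalization time.
* **TCN.** Kernel width 5 is forced by the stated receptive field:
  `1 + (k−1)(1+2+4+8) = 61 ⟹ k = 5`. Convolutions are causal by
  left-padding; causality and the receptive-field formula are verified
  by perturbation probing. No normalization inside the TCN (batch
  statistics would couple timesteps and break strict causality);
  normalization lives in the trunk.
* **Attention.** Each modality summary is projected to queries/keys
  (d_k = 64) and values; the 3×3 score matrix is softmaxed row-wise over
  the key modality (the softmax axis is not dictated by the formula; the
  row convention keeps each query's weights on the simplex) and the
  fused vector is the mean over query rows of the attention-weighted
  values, projected to 512.
* **Open routing points** resolved as: fusion happens before the
  spatiotemporal core; the fused vector reaches the GCN by compression
  to 24 dims and broadcast-concatenation onto each joint's embedding;
  temporal pooling is a mean over frames. Ablation configurations
  (single modality, single task) bypass attention by averaging available
  summaries.
* **Implementation.** The network runs on a small reverse-mode autodiff
  core over numpy arrays written for this package and gradient-checked
  against central finite differences. Default hidden sizes (GCN 48,
  TCN 48 channels, node embeddings 24) are chosen so a full training run
  fits comfortably in desk-scale CPU budgets; the parameter count is a
  pure function of the configuration and is exposed, not asserted
  against any external figure (the appearance branch differs from a
  pretrained backbone by design).

## Losses and training

* Asymmetry: cross-entropy; the training loop uses the class-weighted
  variant (inverse train-split proportions, mean-one normalized), which
  is what the minority hip class needs; the unweighted formula is the
  public op. Risk: focal loss with γ = 2 and α = 3.0/1.5/1.0 for
  high/medium/low.
* Joint objective: `Σ L_i/(2σ_i²) + Σ log σ_i + λ‖Θ‖²` with learned
  log-parametrized task noises (σ > 0 structurally; both initialized at
  σ = 1, i.e. the fixed equal-weighting w = 0.5 baseline). The L2 term
  (λ = 1e−4) is applied once, as AdamW decoupled weight decay — not
  added to the gradient a second time. Log arguments clamp at 1e−12.
* Protocol: AdamW, lr 1e−4, batch 32, at most 100 epochs, early stopping
  when the validation joint loss fails to improve for 10 consecutive
  epochs; 70/15/15 split. Augmentation: horizontal flip (p = 0.5, flips
  the handedness flag, labels unchanged by mirror invariance), temporal
  jitter ±5 frames with edge replication, Gaussian keypoint noise
  σ = 0.01, crop-scale 0.8–1.0 and brightness/contrast ±0.2 on the
  rendered appearance grid; kinematic features are recomputed after
  geometric augmentation. Everything is seeded; equal seeds give
  bit-identical histories.

## Evaluation

Per-class precision/recall/F1 (macro-F1 = unweighted mean over classes
present in the truth), one-vs-rest AUC per class (absent classes are
excluded from macro averages with a warning), confusion matrices,
binary high-risk sensitivity/specificity/PPV/NPV, and stratification by
stroke type and age group (12–14 vs 15–17, or single years). Keypoint
accuracy uses PCK@50: a joint is correct when its error is at most half
the per-frame torso diameter (left shoulder to right hip); the boundary
is inclusive.

## Problem sizes used in the shipped checks

The sanity gates run at desk scale as the package's own test conditions:
the end-to-end gate trains on a 600-sample cohort (noise 0.005, default
effect ranges) for at most 30 epochs and requires validation macro-F1
≥ 0.90 (asymmetry) and one-vs-rest AUC ≥ 0.90 (risk); mirror invariance
is checked over 1,000 random noisy samples; the loss and vertex-slope
identities over 10,000 random points each. These bounds are artifact
sanity gates on synthetic data; they are not reproductions of any
real-data result, and passing them says nothing about accuracy on real
video-derived keypoints (imperfect pose estimation, one-armed strokes,
occlusion and camera motion are all absent from the generator).

## Known limitations

* The default thoracic proxy nullifies the spinal-flexion indicator on
  plain COCO-17 input (see above); real deployments need a mid-spine
  estimate.
* The rule labeler makes "normal" and "low-risk" logically equivalent;
  expert-labeled data where they differ cannot be emulated
  rule-consistently.
* Shoulder "rotation" from keypoints is a geometric surrogate for
  clinical internal/external rotation, which is not observable from 17
  joints.
* The synthetic symmetric-base-motion assumption means effect sizes, not
  realism, are calibrated; transfer to real strokes is untested by
  construction.
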