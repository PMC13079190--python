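# strokesym

Posture-asymmetry recognition and biomechanical injury-risk screening for
adolescent table-tennis strokes, from 17-keypoint motion sequences.

Adolescent racquet-sport athletes load one side of the body far more than
the other during the years when their skeletons are still maturing.
Persistent left–right imbalances of the shoulder girdle, trunk and pelvis
are established precursors of rotator-cuff and lumbar pathology, and
screening for them today relies on subjective visual assessment.
`strokesym` is a tested implementation of a quantitative screening
pipeline for coaches, sports-medicine practitioners and movement-science
researchers: it turns a stroke's keypoint trajectory into six asymmetry
indicators, applies adolescent clinical threshold rules to label the
asymmetry type and stratify injury risk, and trains a multimodal neural
classifier that automates the same judgment from raw sequences.

## What it computes

For each sliding window of a stroke (17 COCO-style keypoints per frame):

* shoulder rotation difference `Δθ = |θ_r − θ_l|` (degrees) and shoulder
  height difference `Δh = |y_r − y_l| / H_body` (dimensionless);
* spinal lateral flexion `α = arctan(2a·x_vertex) = arctan(−b)` from the
  quadratic `y = ax² + bx + c` interpolated through cervical, thoracic and
  lumbar landmarks;
* trunk rotation (shoulder axis vs hip axis in the transverse plane),
  hip flexion difference, and pelvic obliquity
  `γ = arctan((h_r − h_l)/d_hip)`.

Threshold rules (adolescent defaults, roughly 10–15 % stricter than adult
references): shoulder asymmetry at `Δθ > 15°` or `Δh > 0.05`; trunk
asymmetry at `|α| > 8°`; hip asymmetry at `Δθ_hip > 10°` or `|γ| > 5°`.
Risk level counts body segments in simultaneous exceedance: none → low,
one → medium, two or more → high.

The trainable model fuses three modalities (skeleton embedding, a 12-d
kinematic descriptor through a 64-128-128 MLP, and 256-d per-frame
appearance features) by cross-modal attention into a 512-d vector, models
space with a 3-layer GCN over a sport-weighted skeleton graph (racket-arm
chain ×1.5, cross-lateral connections ×1.3), models time with a 4-layer
causal dilated TCN (dilations 2^i, kernel 5, receptive field 61 frames),
and ends in dual heads (4-class asymmetry, 3-level risk) trained with
class-weighted cross-entropy + focal loss under learned uncertainty
weighting `w_i = 1/(2σ_i²)`.

Because the reference stroke corpus is access-restricted, the package
ships a first-class synthetic generator whose injected asymmetries are
exactly recoverable by the measurement chain, making every stage testable.

## Worked example

```python
import numpy as np
import strokesym as ss

# a noise-free forehand drive with a 25.8 deg shoulder-rotation asymmetry
sample = ss.generate_stroke(
    ss.default_template("forehand_drive"),
    ss.AsymmetryParams(shoulder_rot_asym=25.8, spine_flexion=12.0),
    seed=1,
)
ind = ss.indicator_series(sample.keypoints, body_height=sample.body_height)
print(round(ind[20, 0], 1))        # shoulder rotation diff at contact frame
print(sample.y_asym.name, sample.y_injury.name)
```

prints

```
25.8
SHOULDER HIGH
```

The measured indicator at the contact frame equals the injected 25.8°;
shoulder and trunk both exceed their thresholds, so the rule labeler
reports the dominant-excess segment (shoulder) and a high risk level
(two segments involved). The scikit-learn-style estimators wrap the same
machinery:

```python
samples, manifest = ss.generate_cohort(ss.CohortConfig(n_samples=600, seed=11,
                                                       noise_std=0.005))
clf = ss.MultimodalStrokeClassifier(max_epochs=30, seed=1).fit(samples)
proba = clf.predict_risk_proba(samples[:3])
```

A command-line interface mirrors the library
(`strokesym simulate | assess | train | evaluate | report`):

```bash
strokesym simulate --seed 3 --n-samples 100 --out-dir cohort/
strokesym assess clip.csv --body-height 1.62 --out results/clip
```

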