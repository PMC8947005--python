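# mlshift

Automatic, keypoint-based measurement of **midline shift (MLS)** on axial
head CT. Midline shift — the lateral displacement of midline brain
structures by a mass lesion — is one of the most consequential numbers a
radiologist reads off a head CT: a shift of a few millimetres changes
triage, and shifts above 5 mm weigh heavily in surgical decisions. This
package implements the measurement the way a landmark-detection pipeline
does it, and ships a synthetic phantom test bench so the entire pipeline
can be trained and validated without any clinical data.

It is intended for researchers building or evaluating automatic MLS
readers: the geometry, preprocessing, evaluation metrics and training
harness are the reusable parts; the phantom generator provides exact
ground truth for testing them.

## The measurement

On one axial slice, four landmarks are placed: the anterior and posterior
ends of the falx cerebri (which span the *ideal* midline) and the anterior
and posterior ends of the septum pellucidum (which is displaced by mass
effect). With landmark coordinates **p** in pixels and spacing *(s_row,
s_col)* in mm, the per-slice shift is

```
MLS_slice = || mid(falx_ant, falx_post) − mid(sept_ant, sept_post) ||  (in mm)
MLS_scan  = max over slices of MLS_slice
```

Landmarks are found by a two-stage detector in the Keypoint R-CNN family:
a region-proposal stage locates the brain (the ground-truth box is the
falx line scaled by 1.2, with width 0.8 × height), and classification /
box-regression / keypoint heads read each proposal, the keypoint head
predicting one spatial heatmap per landmark. Slice images are prepared by
resizing to 512×512, stacking the 3 adjacent slices as channels, and
windowing the channels with (level, width) = (80, 200), (40, 380) and
(600, 2800) HU, normalised to (0, 1).

Cohort agreement is reported as mean absolute error (mm), ICC(2,1)
(two-way random effects, absolute agreement), and sensitivity/specificity
of detecting MLS strictly greater than 2 / 5 / 10 mm.

Because the full-scale backbone is GPU-sized, the detector is
size-configurable: `backbone_depth="tiny"` is a small strided CNN with the
same two-stage, three-head structure that trains on phantoms in minutes on
one CPU; `"fpn50"` is a reduced-width residual feature-pyramid variant
with the same contract. The neural-network layers (im2col convolutions,
explicit backprop, Adam) are implemented in numpy inside the package.

## Worked example

```python
import numpy as np
import mlshift as m

# a synthetic head with a known 7.5 mm shift and an acute subdural lesion
spec = m.PhantomSpec(patient_id="P0001", scan_id="P0001_S0",
                     true_mls_mm=7.5, lesion_type_label="acute_SDH", seed=7)
scan = m.generate_phantom(spec)
print(f"slices: {scan.volume.n_slices}, annotated: {len(scan.annotations)}")

# noise-free oracle detector: the pipeline recovers the construction exactly
result = m.run_pipeline(scan.volume, m.OracleDetector(scan.annotations))
print(f"scan MLS: {result.scan_mls_mm:.3f} mm at slice {result.argmax_slice_index}")

# with 2 px landmark noise the measurement degrades the way a real reader does
noisy = m.OracleDetector(scan.annotations, sigma_px=2.0,
                         rng=np.random.default_rng(0))
print(f"with 2 px keypoint noise: {m.run_pipeline(scan.volume, noisy).scan_mls_mm:.3f} mm")
```

prints

```
slices: 14, annotated: 7
scan MLS: 7.500 mm at slice 7
with 2 px keypoint noise: 6.483 mm
```

The 7.500 mm is the per-scan maximum over the 7 annotated slices and
matches the phantom's construction; under landmark noise the measured
value moves by roughly the noise scale (2 px ≈ 1.8 mm here), which is what
the cohort-level noise-response analysis quantifies.

Training a desk-scale detector end to end:

```python
parts = m.build_dataset(30, "uniform:0,15", seed=11)        # 8:1:1 by patient
train = m.samples_from_scans(parts["train"])                 # ~330 slices
valid = m.samples_from_scans(parts["valid"])
cfg = m.DetectorConfig(epochs=30, lr_initial=1e-3, seed=7)
model, log = m.train_detector(train, valid, cfg)
res = m.run_pipeline(parts["valid"][0].volume, model)
```

A command-line interface mirrors this: `mlshift generate-phantoms`,
`mlshift train`, `mlshift predict`, `mlshift evaluate`.

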