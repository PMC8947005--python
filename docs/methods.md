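# Methods

## The measurement model

Midline shift is measured per axial slice from four landmarks: the
anterior and posterior attachments of the falx cerebri, and the anterior
and posterior ends of the septum pellucidum. The falx endpoints define the
ideal midline; the slice-level MLS is the Euclidean distance, in mm,
between the midpoint of the falx line and the midpoint of the septum
segment, with each pixel axis scaled by its spacing before the norm. The
scan-level MLS is the maximum over slices (ties broken to the lowest slice
index, for determinism). MLS is reported unsigned; laterality is not
encoded.

Two readings of the slice-level geometry exist: the literal
midpoint-to-midpoint distance, and the component of that displacement
perpendicular to the falx line. The package defaults to
`midpoint_distance` and exposes `perpendicular_to_falx` as an explicit
mode on `compute_mls_slice`, because the two differ whenever the septum
midpoint is displaced along the falx as well as across it. All MLS values
are computed in native pixel space with native spacing; the model-input
resize never enters the measurement.

Whether landmarks come from a human annotator, the oracle test double or
the trained detector, the same geometry code runs — provenance is carried
in `MLSResult.source`.

## Preprocessing

Each slice becomes a 3-channel 512×512 input: the three spatially adjacent
slices (edge slices replicated at the volume boundary) are bilinearly
resized to 512×512 and each channel is windowed with its own (level,
width) pair — (80, 200) subdural-type, (40, 380) soft tissue, (600, 2800)
bone — mapping [level−width/2, level+width/2] linearly to [0, 1] with
clipping. One window per adjacent-slice channel keeps the input 3-channel;
applying all three windows to all three slices would yield nine. Windowing
happens after the resize, on interpolated HU. The resize preserves the
physical field of view: effective spacing is native spacing × native size
/ 512, and annotations are mapped by the same per-axis scale factors.

## Detector

The detector is a two-stage keypoint model: a convolutional backbone, a
region-proposal stage with one anchor per feature cell (objectness +
box-delta regression against the landmark-derived ground-truth box), and a
second stage that crops the top proposal with bilinear ROI alignment and
feeds classification, box-refinement and keypoint heads. The keypoint head
emits one K×K heatmap per landmark inside the proposal (K = 32 by
default), trained with cross-entropy against a Gaussian-smoothed target
(σ = 1 cell) and decoded at inference by the argmax cell refined with a
local 3×3 centroid — a global soft-argmax was rejected because a
multi-modal heatmap (septum mass split between its true position and the
midline) averages the modes and biases the landmark toward zero shift. At
inference the keypoint head reads the refined detection box, so decoded
landmarks are consistent with the returned box. One instance per slice is
kept (a brain appears once); slices scoring below the threshold (default
0.5) contribute no measurement.

During training, stage two sees both a jittered copy of the ground-truth
box and the RPN's current top proposal (labelled by IoU ≥ 0.5 / < 0.3).
Without the proposal path the classifier only ever meets ground-truth-
shaped boxes and rejects its own proposals at inference.

The ground-truth box is the falx line scaled by 1.2 (box height), with
width 0.8 × height, axis-aligned and centred on the falx midpoint. With
the falx within ~37° of vertical this box contains both falx endpoints;
the phantoms and any plausible axial anatomy satisfy this by a wide
margin.

Since no GPU framework is assumed, the layers (im2col convolution, ReLU,
linear, nearest-neighbour upsampling) and Adam are implemented in numpy
with explicit backward passes. Two backbones share the downstream
contract: `tiny` (three strided 3×3 convolutions, stride 4, 24/48/48
channels) for CPU-scale training, and `fpn50`, a reduced-width residual
feature-pyramid (stem + three residual stages, 1×1 laterals, top-down 2×
upsampling) that mirrors the full-scale architecture structurally and
accepts pretrained backbone weights from disk as an optional hook. The
detector works at an internal resolution (default 128; 512-px inputs are
block-averaged down, predictions mapped back), which keeps a training run
of ~300 slices × 30 epochs in the minutes range on one CPU.

Training defaults follow the reference recipe: Adam (β₁ = 0.9,
β₂ = 0.999, weight decay 0), initial learning rate 1e-4 divided by 10
after 100 of 200 epochs, batch size 16. Desk-scale runs use fewer epochs
and a larger initial rate (30 epochs at 1e-3 with a ×5 drop at epoch 20 in
the tests and acceptance runs), because ~600 optimizer steps at 1e-4 leave
the tiny model visibly under-trained, and the late drop measurably
sharpens landmark localisation.
Augmentations (each gated by a config flag, applied per sample with fixed
probabilities): sagittal flip, which mirrors x and preserves landmark
identities; a small random affine (±8° rotation, ±5 % translation,
0.95–1.05 scale) applied identically to image and landmarks, resampled up
to 10 times if a landmark would leave the image and then skipped; random
rectangular erasing (image only); and simplified metal streaks in the
normalised intensity domain.

ROI alignment is 8×8; a 16×16 grid was tried and did not improve landmark
error at this feature resolution, while backbone width did — the
septum-vs-midline discrimination is feature-limited, not sampling-limited.

## Phantoms

The synthetic scans are deliberately schematic heads, not anatomy: an
elliptical bone-density skull (≈1000 HU, mild spherical tapering along z)
around brain parenchyma (30 HU, Gaussian noise σ = 3 HU), air background
(−1000 HU), a 60 HU falx line on the midline, CSF-density lateral
ventricles (8 HU) flanking a septum segment, and optionally one of six
hemorrhage-class density templates (parenchymal blob, intraventricular
blob, parafalcine layer, acute/chronic subdural crescent, epidural lens)
plus alternating-sign linear metal streaks. Default geometry: 256×256
pixels at 0.9 mm in-plane, 14 slices at 5 mm — a typical axial
reconstruction; the generator emulates cohort *structure* (lesion-class
stratification, per-patient grouping, a controllable MLS distribution),
not radiological appearance.

The septum (with its ventricles) is displaced perpendicular to the falx by
a per-slice raised-cosine profile over the ventricle-level band, peaking
at exactly the requested `true_mls_mm` at the mid-ventricle slice, so the
emitted float-precision annotations reproduce the requested scan MLS
exactly and every phantom carries its own ground truth. A shift that would
push the septum outside the inner skull is rejected. Annotations exist
only on slices where the septum is drawn; downstream code never assumes
dense annotation. Generation is byte-deterministic under the spec seed,
and a geometry-only mode (`render_voxels=False`) supports large
cohort-level Monte-Carlo runs that never look at pixels.

Passing tests on phantoms show that the geometry, aggregation, training
harness and metrics are correct and that the detector can learn this
family of images; they say nothing about performance on clinical CT, where
contrast, anatomy variation and artifacts are far richer.

## Dataset assembly

Cohorts are split by patient, never by scan: within each lesion class,
patients are partitioned train/validation/test at 8:1:1 by
largest-remainder rounding (a class with fewer than 3 patients goes
entirely to train, with a warning). The 2 px-noise oracle cohorts use 300–
500 scans; detector runs use 30 patients (~330 slices), sizes chosen so
the full suite runs in minutes on one CPU.

## Evaluation

Scan-level only. MAE is the mean absolute difference of paired per-scan
MLS (the maximum is also reported); ICC is the two-way random-effects,
absolute-agreement, single-rater form ICC(2,1) — computed via pingouin,
with the choice fixed because the absolute-agreement form penalises
systematic bias between readers; sensitivity/specificity use a strict
"greater than" cutoff at 2/5/10 mm (a scan at exactly the cutoff is
negative). A prediction with no detected slice scores 0 mm and stays in
the cohort — a missed detection must not silently improve the statistics.
When a reference cohort has no positives (or negatives) at a cutoff, the
undefined rate is reported as absent, not zero. ICC on fewer than 3
subjects is reported as NaN.

One behaviour worth knowing: because the scan value is a maximum over
noisy per-slice values, landmark noise biases the scan MLS upward, which
depresses specificity at low cutoffs in noisy cohorts. This is a property
of the max-aggregation measurement itself and is visible in the
noise-response numbers.

## Known limitations

- Phantom realism is intentionally minimal; no sinogram-based artifact
  physics, no skull stripping, no gantry-tilt handling.
- The tiny detector's landmark precision is limited by its internal
  resolution and heatmap granularity (about one heatmap cell, ≈4–6 mm at
  the default settings); it demonstrates learnability, not clinical
  accuracy.
- The per-scan maximum is sensitive to a single mislocalised slice; no
  outlier suppression is applied because the scan definition is the
  maximum.
- DICOM ingestion expects a single-orientation axial series with rescale
  and spacing metadata present; anything else is a hard error by design.
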