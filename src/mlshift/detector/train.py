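"""Training harness and inference wrappers for the keypoint detector.

Training samples pair a preprocessed 512-pixel model input with the
ground-truth landmarks (in 512-pixel coordinates) and the landmark-derived
bounding box; slices without a measurable septum enter as background
samples. The detector itself works at a reduced internal resolution
(``cfg.image_size``), reached by block-averaging, and predictions are mapped
back through the resize chain to native pixel space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..geometry import (
    BoundingBox,
    KeypointSet,
    keypoints_to_bbox,
    rescale_keypoints,
)
from ..phantom import LabeledScan
from ..preprocess import DEFAULT_WINDOWS, ModelInput, preprocess_volume
from .augment import augment_sample
from .model import Detection, DetectorConfig, KeypointDetector, learning_rate

__all__ = [
    "TrainingSample",
    "samples_from_scans",
    "train_detector",
    "predict_keypoints",
]


@dataclass
class TrainingSample:
    """One slice with optional ground truth (coordinates in 512-px space)."""

    model_input: ModelInput
    keypoints: Optional[KeypointSet] = None
    bbox: Optional[BoundingBox] = None

    @property
    def is_positive(self) -> bool:
        return self.keypoints is not None


def samples_from_scans(
    scans: Sequence[LabeledScan],
    windows=DEFAULT_WINDOWS,
    target: int = 512,
    include_negatives: bool = True,
) -> list[TrainingSample]:
    """Preprocess labelled scans into per-slice training samples.

    Annotated slices get landmarks rescaled into the model-input space and a
    derived bounding box; unannotated slices become background samples when
    ``include_negatives`` is set (the classifier must learn to reject
    slices where the septum is not measurable).
    """
    samples: list[TrainingSample] = []
    for scan in scans:
        if scan.volume is None:
            raise ValueError(f"scan {scan.scan_id!r} was generated without voxels")
        native = scan.volume.slice_shape
        ann_by_slice = {r.slice_index: r for r in scan.annotations}
        inputs = preprocess_volume(scan.volume, windows, target=target)
        for mi in inputs:
            rec = ann_by_slice.get(mi.center_slice_index)
            if rec is not None:
                kp = rescale_keypoints(rec.keypoints, native, (target, target))
                samples.append(
                    TrainingSample(mi, kp, keypoints_to_bbox(kp, (target, target)))
                )
            elif include_negatives:
                samples.append(TrainingSample(mi))
    return samples


def _downscale(pixels: np.ndarray, size: int) -> np.ndarray:
    """Block-average a (3, T, T) image down to (3, size, size)."""
    t = pixels.shape[-1]
    if t == size:
        return pixels.astype(np.float32)
    if t % size:
        raise ValueError(f"internal size {size} must divide input size {t}")
    f = t // size
    return (
        pixels.reshape(3, size, f, size, f).mean(axis=(2, 4)).astype(np.float32)
    )


def _to_internal(sample: TrainingSample, cfg: DetectorConfig):
    """(image, kp array, box array) at the detector's internal resolution."""
    target = sample.model_input.pixels.shape[-1]
    scale = cfg.image_size / target
    img = _downscale(sample.model_input.pixels, cfg.image_size)
    if sample.keypoints is None:
        return img, None, None
    kp = sample.keypoints.as_array() * scale
    box = np.array(
        [sample.bbox.x_min, sample.bbox.y_min, sample.bbox.x_max, sample.bbox.y_max]
    ) * scale
    return img, kp, box


def train_detector(
    train: Sequence[TrainingSample],
    valid: Sequence[TrainingSample],
    cfg: DetectorConfig,
) -> tuple[KeypointDetector, list[dict]]:
    """Train the two-stage detector; returns the model and per-epoch log.

    Each log entry carries the learning rate, the four loss terms (region
    proposal, classification, box regression, keypoint) and the validation
    mean keypoint error in mm. Epoch-0 losses are deterministic under
    ``cfg.seed``. Raises on an empty dataset or a non-finite loss.
    """
    if len(train) == 0:
        raise ValueError("empty training dataset")
    model = KeypointDetector(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = model.make_optimizer(cfg.lr_initial)

    internal = [_to_internal(s, cfg) for s in train]
    val_internal = [_to_internal(s, cfg) for s in valid]
    # mm per internal pixel, for the validation keypoint error
    target = train[0].model_input.pixels.shape[-1]
    eff = train[0].model_input.effective_spacing
    mm_per_px = (eff[0] * target / cfg.image_size, eff[1] * target / cfg.image_size)

    log: list[dict] = []
    order = np.arange(len(internal))
    for epoch in range(cfg.epochs):
        lr = learning_rate(cfg, epoch)
        optimizer.lr = lr
        rng.shuffle(order)
        sums = {"loss_rpn_obj": 0.0, "loss_rpn_box": 0.0, "loss_cls": 0.0,
                "loss_box": 0.0, "loss_kp": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            images, boxes, kps = [], [], []
            for j in idx:
                img, kp, box = internal[j]
                kp_set = KeypointSet.from_array(kp) if kp is not None else None
                img, kp_set = augment_sample(img, kp_set, cfg, rng)
                if kp_set is not None:
                    kp = kp_set.as_array()
                    b = keypoints_to_bbox(kp_set, (cfg.image_size, cfg.image_size))
                    box = np.array([b.x_min, b.y_min, b.x_max, b.y_max])
                else:
                    kp, box = None, None
                images.append(img)
                boxes.append(box)
                kps.append(kp)
            model.zero_grad()
            losses = model.training_step(np.stack(images), boxes, kps, rng)
            total = sum(losses.values())
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {losses}"
                )
            optimizer.step()
            for k_ in sums:
                sums[k_] += losses[k_]
            n_batches += 1
        entry = {k_: v / n_batches for k_, v in sums.items()}
        entry["epoch"] = epoch
        entry["lr"] = lr
        entry["loss_total"] = sum(sums.values()) / n_batches
        entry["val_kp_error_mm"] = _validation_error(model, val_internal, mm_per_px)
        log.append(entry)
    return model, log


def _validation_error(model, val_internal, mm_per_px) -> float:
    """Mean landmark error (mm) over annotated validation slices; detected
    slices only, NaN when nothing is detected."""
    pos = [(img, kp) for img, kp, _ in val_internal if kp is not None]
    if not pos:
        return float("nan")
    errs = []
    for start in range(0, len(pos), 16):
        chunk = pos[start : start + 16]
        dets = model.detect(np.stack([c[0] for c in chunk]))
        for (_, kp), det in zip(chunk, dets):
            if det is None:
                continue
            d = det.keypoints.as_array() - kp
            d_mm = d * np.array([mm_per_px[1], mm_per_px[0]])
            errs.append(float(np.linalg.norm(d_mm, axis=1).mean()))
    return float(np.mean(errs)) if errs else float("nan")


def predict_keypoints(
    model: KeypointDetector,
    inputs: Sequence[ModelInput],
    score_threshold: Optional[float] = None,
    native_size: Optional[tuple[int, int]] = None,
) -> dict[int, Optional[Detection]]:
    """Run the detector over preprocessed slices of one scan.

    Returns a mapping from slice index to the single best detection (or
    None below the score threshold). Keypoints and boxes are rescaled to
    native pixel space when ``native_size = (rows, cols)`` is given,
    otherwise they stay in the model-input (512-px) space.
    """
    if score_threshold is not None:
        # a threshold above 1 can never be reached by a sigmoid score
        model.cfg.score_threshold = score_threshold
    out: dict[int, Optional[Detection]] = {}
    if not inputs:
        return out
    target = inputs[0].pixels.shape[-1]
    scale_to_target = target / model.cfg.image_size
    order = [mi.center_slice_index for mi in inputs]
    for start in range(0, len(inputs), 16):
        chunk = inputs[start : start + 16]
        batch = np.stack([_downscale(mi.pixels, model.cfg.image_size) for mi in chunk])
        for mi, det in zip(chunk, model.detect(batch)):
            if det is None:
                out[mi.center_slice_index] = None
                continue
            kp = KeypointSet.from_array(det.keypoints.as_array() * scale_to_target)
            box = BoundingBox(
                det.box.x_min * scale_to_target,
                det.box.y_min * scale_to_target,
                det.box.x_max * scale_to_target,
                det.box.y_max * scale_to_target,
            )
            if native_size is not None:
                kp = rescale_keypoints(kp, (target, target), native_size)
                sx = native_size[1] / target
                sy = native_size[0] / target
                box = BoundingBox(
                    box.x_min * sx, box.y_min * sy, box.x_max * sx, box.y_max * sy
                )
            out[mi.center_slice_index] = Detection(box, det.score, kp)
    assert sorted(out) == sorted(order)
    return out
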