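"""Two-stage keypoint detector: region proposals, then three task heads.

The architecture follows the Keypoint R-CNN family: a convolutional backbone
produces a feature map; a region-proposal network (RPN) scores one anchor
per feature cell and regresses it onto the brain bounding box; the top
proposal is cropped from the feature map with bilinear ROI alignment and fed
to three heads — classification (is a measurable septum present), bounding-
box refinement, and a keypoint head that predicts one spatial heatmap per
landmark inside the proposal, decoded by soft-argmax.

Two backbone sizes are provided. ``tiny`` is a three-layer strided CNN that
trains on phantoms in minutes on one CPU; ``fpn50`` is a reduced-width
residual feature-pyramid backbone with the same downstream contract (it is
functional but far slower, and ships as the structural mirror of the
full-scale architecture, with an optional hook for loading pretrained
weights from disk). Exactly one instance is detected per slice — a brain
appears once — and slices whose score falls below the threshold yield no
detection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from ..geometry import BoundingBox, KeypointSet
from .nn import Adam, Conv2d, Linear, Module, ReLU, Upsample2x

__all__ = ["DetectorConfig", "Detection", "KeypointDetector", "learning_rate"]


@dataclass
class DetectorConfig:
    """Detector architecture and training schedule.

    The schedule defaults are the reference training recipe (Adam with
    betas (0.9, 0.999) and zero weight decay, initial learning rate 1e-4
    divided by 10 after 100 of 200 epochs, batch size 16); desk-scale runs
    override ``epochs`` and usually ``lr_initial``. ``image_size`` is the
    internal resolution the detector works at: 512-pixel model inputs are
    block-averaged down to it, and predictions are mapped back.
    """

    backbone_depth: str = "tiny"  # {tiny | fpn50}
    image_size: int = 128
    n_keypoints: int = 4
    epochs: int = 200
    lr_initial: float = 1e-4
    lr_drop_epoch: int = 100
    lr_drop_factor: float = 10.0
    batch_size: int = 16
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    augment_flip_sagittal: bool = True
    augment_affine: bool = True
    augment_erasing: bool = True
    augment_metal_streaks: bool = True
    seed: int = 0
    # architecture details (defaults of the family; not prescribed upstream)
    heatmap_size: int = 32
    roi_align_size: int = 8
    tiny_channels: tuple = (24, 48, 48)
    hidden_dim: int = 256
    anchor_scale: float = 0.9  # anchor height / image_size
    box_aspect: float = 0.8  # anchor width / height, matches the GT box rule
    score_threshold: float = 0.5
    pretrained_backbone: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_keypoints != 4:
            raise ValueError("the midline-shift detector uses exactly 4 keypoints")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if self.backbone_depth not in ("tiny", "fpn50"):
            raise ValueError(f"unknown backbone {self.backbone_depth!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def learning_rate(cfg: DetectorConfig, epoch: int) -> float:
    """Step schedule: ``lr_initial``, divided by ``lr_drop_factor`` once
    ``epoch >= lr_drop_epoch`` (0-based epochs)."""
    if epoch >= cfg.lr_drop_epoch:
        return cfg.lr_initial / cfg.lr_drop_factor
    return cfg.lr_initial


@dataclass
class Detection:
    """One detected instance on a slice (pixel coords of the prediction space)."""

    box: BoundingBox
    score: float
    keypoints: KeypointSet


# ---------------------------------------------------------------- backbones


class _Sequential(Module):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class TinyBackbone(_Sequential):
    """3-conv strided CNN; stride 4."""

    stride = 4

    def __init__(self, rng, channels=(16, 32, 32)):
        c1, c2, c3 = channels
        self.out_channels = c3
        super().__init__(
            [
                Conv2d(3, c1, 3, stride=2, rng=rng),
                ReLU(),
                Conv2d(c1, c2, 3, stride=2, rng=rng),
                ReLU(),
                Conv2d(c2, c3, 3, stride=1, rng=rng),
                ReLU(),
            ]
        )


class _ResBlock(Module):
    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, rng=rng)
        self.proj = (
            Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            if (c_in != c_out or stride != 1)
            else None
        )
        self.relu2 = ReLU()

    def forward(self, x):
        self._x = x
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(y + skip)

    def backward(self, dy):
        dsum = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        if self.proj is not None:
            dx = dx + self.proj.backward(dsum)
        else:
            dx = dx + dsum
        return dx


class FPNBackbone(Module):
    """Reduced-width residual pyramid; emits the stride-4 merged level.

    Structurally mirrors a ResNet-FPN: a strided stem, four residual stages,
    1x1 lateral connections and a nearest-neighbour top-down pathway, with a
    3x3 smoothing conv on the finest merged map. Channel widths are scaled
    far below the 50-layer reference so it remains runnable on CPU.
    """

    out_channels = 64
    stride = 4

    def __init__(self, rng):
        self.stem = _Sequential([Conv2d(3, 16, 3, stride=2, rng=rng), ReLU()])
        self.stage1 = _ResBlock(16, 16, 2, rng)  # stride 4
        self.stage2 = _ResBlock(16, 32, 2, rng)  # stride 8
        self.stage3 = _ResBlock(32, 64, 2, rng)  # stride 16
        self.lat1 = Conv2d(16, 64, 1, pad=0, rng=rng)
        self.lat2 = Conv2d(32, 64, 1, pad=0, rng=rng)
        self.lat3 = Conv2d(64, 64, 1, pad=0, rng=rng)
        self.up = Upsample2x()
        self.smooth = Conv2d(64, 64, 3, rng=rng)

    def forward(self, x):
        s = self.stem.forward(x)
        c1 = self.stage1.forward(s)
        c2 = self.stage2.forward(c1)
        c3 = self.stage3.forward(c2)
        p3 = self.lat3.forward(c3)
        p2 = self.lat2.forward(c2) + self.up.forward(p3)
        p1 = self.lat1.forward(c1) + self.up.forward(p2)
        return self.smooth.forward(p1)

    def backward(self, dy):
        dp1 = self.smooth.backward(dy)
        dc1_lat = self.lat1.backward(dp1)
        dp2 = self.up.backward(dp1)
        dc2_lat = self.lat2.backward(dp2)
        dp3 = self.up.backward(dp2)
        dc3 = self.lat3.backward(dp3)
        dc2 = dc2_lat + self.stage3.backward(dc3)
        dc1 = dc1_lat + self.stage2.backward(dc2)
        ds = self.stage1.backward(dc1)
        return self.stem.backward(ds)


# ------------------------------------------------------------------- heads


class RPNHead(Module):
    """One anchor per cell: objectness logit + 4 box deltas."""

    def __init__(self, c_in, rng):
        self.conv = Conv2d(c_in, c_in, 3, rng=rng)
        self.relu = ReLU()
        self.obj = Conv2d(c_in, 1, 1, pad=0, rng=rng)
        self.box = Conv2d(c_in, 4, 1, pad=0, rng=rng)

    def forward(self, feat):
        h = self.relu.forward(self.conv.forward(feat))
        self._h = h
        return self.obj.forward(h), self.box.forward(h)

    def backward(self, dobj, dbox):
        dh = self.obj.backward(dobj) + self.box.backward(dbox)
        return self.conv.backward(self.relu.backward(dh))


class RoIHead(Module):
    """Shared fc trunk with classification, box-refinement and keypoint heads."""

    def __init__(self, c_in, cfg: DetectorConfig, rng):
        p = cfg.roi_align_size
        k = cfg.heatmap_size
        self.fc1 = Linear(c_in * p * p, cfg.hidden_dim, rng=rng)
        self.relu = ReLU()
        self.cls = Linear(cfg.hidden_dim, 1, rng=rng)
        self.box = Linear(cfg.hidden_dim, 4, rng=rng)
        self.kp = Linear(cfg.hidden_dim, cfg.n_keypoints * k * k, rng=rng)
        self._shape = None

    def forward(self, aligned):
        n = aligned.shape[0]
        self._shape = aligned.shape
        h = self.relu.forward(self.fc1.forward(aligned.reshape(n, -1)))
        return self.cls.forward(h), self.box.forward(h), self.kp.forward(h)

    def backward(self, dcls, dbox, dkp):
        dh = self.cls.backward(dcls) + self.box.backward(dbox) + self.kp.backward(dkp)
        dflat = self.fc1.backward(self.relu.backward(dh))
        return dflat.reshape(self._shape)


# --------------------------------------------------------------- roi align


def _roi_align(feat, box, p, stride):
    """Bilinear crop of one image's feature map to (C, p, p).

    ``feat`` is (C, Hf, Wf); ``box`` is (x0, y0, x1, y1) in input-image
    coordinates. Returns the aligned crop and a cache for the backward pass.
    """
    c, hf, wf = feat.shape
    x0, y0, x1, y1 = box
    xs = x0 + (np.arange(p) + 0.5) * (x1 - x0) / p
    ys = y0 + (np.arange(p) + 0.5) * (y1 - y0) / p
    xf = np.clip(xs / stride - 0.5, 0.0, wf - 1.0)
    yf = np.clip(ys / stride - 0.5, 0.0, hf - 1.0)
    xi = np.clip(np.floor(xf).astype(int), 0, wf - 2)
    yi = np.clip(np.floor(yf).astype(int), 0, hf - 2)
    tx = (xf - xi).astype(np.float32)
    ty = (yf - yi).astype(np.float32)
    w00 = np.outer(1 - ty, 1 - tx)
    w01 = np.outer(1 - ty, tx)
    w10 = np.outer(ty, 1 - tx)
    w11 = np.outer(ty, tx)
    aligned = (
        feat[:, yi[:, None], xi[None, :]] * w00
        + feat[:, yi[:, None], xi[None, :] + 1] * w01
        + feat[:, yi[:, None] + 1, xi[None, :]] * w10
        + feat[:, yi[:, None] + 1, xi[None, :] + 1] * w11
    )
    return aligned.astype(np.float32), (yi, xi, w00, w01, w10, w11)


def _roi_align_backward(daligned, cache, dfeat):
    yi, xi, w00, w01, w10, w11 = cache
    c = dfeat.shape[0]
    ci = np.arange(c)[:, None, None]
    yy = yi[None, :, None]
    xx = xi[None, None, :]
    np.add.at(dfeat, (ci, yy, xx), daligned * w00)
    np.add.at(dfeat, (ci, yy, xx + 1), daligned * w01)
    np.add.at(dfeat, (ci, yy + 1, xx), daligned * w10)
    np.add.at(dfeat, (ci, yy + 1, xx + 1), daligned * w11)


# ------------------------------------------------------------------ boxes


def _iou(boxes, gt):
    """IoU of (M, 4) boxes against one (4,) ground-truth box."""
    x0 = np.maximum(boxes[:, 0], gt[0])
    y0 = np.maximum(boxes[:, 1], gt[1])
    x1 = np.minimum(boxes[:, 2], gt[2])
    y1 = np.minimum(boxes[:, 3], gt[3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_b = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    area_g = (gt[2] - gt[0]) * (gt[3] - gt[1])
    return inter / (area_b + area_g - inter + 1e-9)


def _encode_deltas(anchor, gt):
    """(dx, dy, dw, dh) regression targets from anchor(s) to a GT box."""
    aw = anchor[..., 2] - anchor[..., 0]
    ah = anchor[..., 3] - anchor[..., 1]
    ax = (anchor[..., 0] + anchor[..., 2]) / 2
    ay = (anchor[..., 1] + anchor[..., 3]) / 2
    gw = gt[..., 2] - gt[..., 0]
    gh = gt[..., 3] - gt[..., 1]
    gx = (gt[..., 0] + gt[..., 2]) / 2
    gy = (gt[..., 1] + gt[..., 3]) / 2
    return np.stack(
        [(gx - ax) / aw, (gy - ay) / ah, np.log(gw / aw), np.log(gh / ah)], axis=-1
    )


def _decode_deltas(anchor, deltas):
    aw = anchor[..., 2] - anchor[..., 0]
    ah = anchor[..., 3] - anchor[..., 1]
    ax = (anchor[..., 0] + anchor[..., 2]) / 2
    ay = (anchor[..., 1] + anchor[..., 3]) / 2
    cx = ax + deltas[..., 0] * aw
    cy = ay + deltas[..., 1] * ah
    w = aw * np.exp(np.clip(deltas[..., 2], -4, 4))
    h = ah * np.exp(np.clip(deltas[..., 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


# ------------------------------------------------------------------ losses


def _bce_logits(z, t):
    """Elementwise BCE with logits; returns (loss, dloss/dz)."""
    loss = np.logaddexp(0.0, z) - t * z
    grad = 1.0 / (1.0 + np.exp(-z)) - t
    return loss, grad


def _smooth_l1(d):
    a = np.abs(d)
    loss = np.where(a < 1.0, 0.5 * d * d, a - 0.5)
    grad = np.where(a < 1.0, d, np.sign(d))
    return loss, grad


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ------------------------------------------------------------------- model


class KeypointDetector(Module):
    """The assembled two-stage detector (see module docstring)."""

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.backbone_depth == "tiny":
            self.backbone = TinyBackbone(rng, tuple(cfg.tiny_channels))
        else:
            self.backbone = FPNBackbone(rng)
        c = self.backbone.out_channels
        self.rpn = RPNHead(c, rng)
        self.roi_head = RoIHead(c, cfg, rng)
        self._anchors = None  # lazily built per feature-map size
        if cfg.pretrained_backbone:
            state = np.load(cfg.pretrained_backbone, allow_pickle=False)
            self.backbone.load_state_dict([state[k] for k in sorted(state.files)])

    # -- anchors ------------------------------------------------------

    def anchors_for(self, hf: int, wf: int) -> np.ndarray:
        """(hf*wf, 4) anchor boxes in input-image coordinates."""
        if self._anchors is not None and self._anchors.shape[0] == hf * wf:
            return self._anchors
        s = self.backbone.stride
        ah = self.cfg.anchor_scale * self.cfg.image_size
        aw = self.cfg.box_aspect * ah
        ys, xs = np.mgrid[0:hf, 0:wf]
        cx = (xs.ravel() + 0.5) * s
        cy = (ys.ravel() + 0.5) * s
        self._anchors = np.stack(
            [cx - aw / 2, cy - ah / 2, cx + aw / 2, cy + ah / 2], axis=1
        )
        return self._anchors

    # -- training step ------------------------------------------------

    def training_step(self, images, gt_boxes, gt_keypoints, rng):
        """One forward/backward pass on a batch; returns the loss terms.

        ``images`` is (N, 3, S, S) float32; ``gt_boxes[i]`` is a (4,) array
        or None for a slice without a measurable septum; ``gt_keypoints[i]``
        is a (4, 2) array or None. Gradients are accumulated into the
        parameters (caller zeroes and steps the optimizer).
        """
        cfg = self.cfg
        n = images.shape[0]
        feat = self.backbone.forward(images)
        obj, box_reg = self.rpn.forward(feat)
        _, _, hf, wf = obj.shape
        anchors = self.anchors_for(hf, wf)

        dobj = np.zeros_like(obj)
        dbox = np.zeros_like(box_reg)
        dfeat = np.zeros_like(feat)

        loss_obj = loss_rpn_box = loss_cls = loss_box = loss_kp = 0.0
        n_pos = 0

        # stage-2 ROI batch assembled image by image
        rois, roi_caches, roi_targets = [], [], []
        for i in range(n):
            zi = obj[i, 0].ravel()
            if gt_boxes[i] is not None:
                gt = gt_boxes[i]
                iou = _iou(anchors, gt)
                pos = iou >= 0.5
                pos[np.argmax(iou)] = True
                neg = iou < 0.3
                labels = np.where(pos, 1.0, 0.0)
                use = pos | neg
                w = np.zeros_like(zi)
                w[pos] = 0.5 / max(1, pos.sum())
                w[neg & use] = 0.5 / max(1, (neg & use).sum())
                l, g = _bce_logits(zi, labels)
                loss_obj += float((l * w).sum())
                dobj[i, 0] = (g * w).reshape(hf, wf)
                # box regression on positive anchors
                t = _encode_deltas(anchors[pos], gt[None, :])
                pred = box_reg[i].reshape(4, -1).T[pos]
                l2, g2 = _smooth_l1(pred - t)
                loss_rpn_box += float(l2.mean())
                gfull = np.zeros((anchors.shape[0], 4), dtype=np.float32)
                gfull[pos] = g2 / l2.size
                dbox[i] = gfull.T.reshape(4, hf, wf)
                # stage-2 positive ROI: jittered GT box
                bw, bh = gt[2] - gt[0], gt[3] - gt[1]
                jit = rng.uniform(-0.05, 0.05, 4) * np.array([bw, bh, bw, bh])
                roi = gt + jit
                rois.append((i, roi, 1.0, gt, gt_keypoints[i]))
                n_pos += 1
                # also run the RPN's current top proposal through stage 2,
                # labelled by IoU, so inference-time ROIs match training
                prop = self._top_proposal(obj[i, 0], box_reg[i], anchors)
                if prop is not None:
                    piou = float(_iou(prop[None, :], gt)[0])
                    if piou >= 0.5:
                        rois.append((i, prop, 1.0, gt, gt_keypoints[i]))
                    elif piou < 0.3:
                        rois.append((i, prop, 0.0, None, None))
            else:
                # background slice: every anchor is negative
                l, g = _bce_logits(zi, np.zeros_like(zi))
                loss_obj += float(l.mean())
                dobj[i, 0] = (g / zi.size).reshape(hf, wf)
                # stage-2 negative ROI: jittered anchor-sized centre box
                c = cfg.image_size / 2
                ah = cfg.anchor_scale * cfg.image_size
                aw = cfg.box_aspect * ah
                jit = rng.uniform(-0.08, 0.08, 2) * cfg.image_size
                roi = np.array(
                    [c - aw / 2 + jit[0], c - ah / 2 + jit[1],
                     c + aw / 2 + jit[0], c + ah / 2 + jit[1]]
                )
                rois.append((i, roi, 0.0, None, None))
                prop = self._top_proposal(obj[i, 0], box_reg[i], anchors)
                if prop is not None:
                    rois.append((i, prop, 0.0, None, None))

        dobj /= n
        dbox /= n

        p = cfg.roi_align_size
        aligned = np.zeros((len(rois), self.backbone.out_channels, p, p), np.float32)
        for j, (i, roi, *_rest) in enumerate(rois):
            aligned[j], cache = _roi_align(feat[i], roi, p, self.backbone.stride)
            roi_caches.append(cache)

        cls_logit, box_delta, kp_logit = self.roi_head.forward(aligned)
        k = cfg.heatmap_size

        dcls = np.zeros_like(cls_logit)
        dbox2 = np.zeros_like(box_delta)
        dkp = np.zeros_like(kp_logit)
        cls_targets = np.array([r[2] for r in rois], dtype=np.float32)
        l, g = _bce_logits(cls_logit[:, 0], cls_targets)
        loss_cls = float(l.mean())
        dcls[:, 0] = g / len(rois)

        pos_idx = [j for j, r in enumerate(rois) if r[2] == 1.0]
        if pos_idx:
            for j in pos_idx:
                _, roi, _, gt, kps = rois[j]
                t = _encode_deltas(roi, gt)
                l2, g2 = _smooth_l1(box_delta[j] - t)
                loss_box += float(l2.mean()) / len(pos_idx)
                dbox2[j] = g2 / (l2.size * len(pos_idx))
                # keypoint heatmaps: soft (Gaussian) target in ROI cell units
                zz = kp_logit[j].reshape(cfg.n_keypoints, k * k)
                probs = _softmax(zz, axis=1)
                gx, gy = np.meshgrid(np.arange(k), np.arange(k))
                targets = np.zeros_like(zz)
                for q in range(cfg.n_keypoints):
                    u = (kps[q, 0] - roi[0]) / (roi[2] - roi[0]) * k - 0.5
                    v = (kps[q, 1] - roi[1]) / (roi[3] - roi[1]) * k - 0.5
                    d2 = (gx - u) ** 2 + (gy - v) ** 2
                    tq = np.exp(-d2 / 2.0)
                    targets[q] = (tq / tq.sum()).ravel()
                kp_w = 2.0  # keypoint accuracy is the pipeline's end product
                loss_kp += kp_w * float(
                    -(targets * np.log(probs + 1e-12)).sum() / cfg.n_keypoints
                ) / len(pos_idx)
                dkp[j] = (
                    kp_w * (probs - targets) / (cfg.n_keypoints * len(pos_idx))
                ).ravel()

        daligned = self.roi_head.backward(dcls, dbox2, dkp)
        for j, (i, roi, *_rest) in enumerate(rois):
            _roi_align_backward(daligned[j], roi_caches[j], dfeat[i])
        dfeat += self.rpn.backward(dobj, dbox)
        self.backbone.backward(dfeat)

        return {
            "loss_rpn_obj": loss_obj / n,
            "loss_rpn_box": loss_rpn_box / max(1, n_pos),
            "loss_cls": loss_cls,
            "loss_box": loss_box,
            "loss_kp": loss_kp,
        }

    def _top_proposal(self, obj_map, box_map, anchors):
        """Decode the current highest-scoring RPN proposal (no gradient)."""
        best = int(np.argmax(obj_map.ravel()))
        deltas = box_map.reshape(4, -1).T[best]
        roi = _decode_deltas(anchors[best], deltas)
        roi = np.clip(roi, 0, self.cfg.image_size - 1)
        if roi[2] - roi[0] < 2 or roi[3] - roi[1] < 2:
            return None
        return roi

    # -- inference ----------------------------------------------------

    def detect(self, images: np.ndarray) -> list[Optional[Detection]]:
        """Detect at most one instance per image of an (N, 3, S, S) batch.

        Returns, per image, a :class:`Detection` in the detector's own
        image coordinates, or None when the classification score falls
        below ``cfg.score_threshold``.
        """
        cfg = self.cfg
        feat = self.backbone.forward(images)
        obj, box_reg = self.rpn.forward(feat)
        n, _, hf, wf = obj.shape
        anchors = self.anchors_for(hf, wf)
        size = cfg.image_size
        p, k = cfg.roi_align_size, cfg.heatmap_size
        out: list[Optional[Detection]] = []
        for i in range(n):
            scores = obj[i, 0].ravel()
            best = int(np.argmax(scores))
            deltas = box_reg[i].reshape(4, -1).T[best]
            roi = _decode_deltas(anchors[best], deltas)
            roi = np.clip(roi, 0, size - 1)
            if roi[2] - roi[0] < 2 or roi[3] - roi[1] < 2:
                out.append(None)
                continue
            aligned, _ = _roi_align(feat[i], roi, p, self.backbone.stride)
            cls_logit, box_delta, kp_logit = self.roi_head.forward(aligned[None])
            score = float(1.0 / (1.0 + np.exp(-cls_logit[0, 0])))
            if score < cfg.score_threshold:
                out.append(None)
                continue
            refined = np.clip(_decode_deltas(roi, box_delta[0]), 0, size - 1)
            if refined[2] - refined[0] >= 2 and refined[3] - refined[1] >= 2:
                # the keypoint head reads the final detection box, so the
                # decoded landmarks are consistent with the returned box
                roi = refined
                aligned, _ = _roi_align(feat[i], roi, p, self.backbone.stride)
                _, _, kp_logit = self.roi_head.forward(aligned[None])
            probs = _softmax(kp_logit[0].reshape(cfg.n_keypoints, k * k), axis=1)
            pk = probs.reshape(cfg.n_keypoints, k, k)
            # argmax cell with a local centroid refinement: robust to a
            # multi-modal heatmap (a global expectation would average the
            # modes and bias the landmark toward the midline)
            u = np.empty(cfg.n_keypoints)
            v = np.empty(cfg.n_keypoints)
            for q in range(cfg.n_keypoints):
                flat = int(np.argmax(pk[q]))
                vy, vx = divmod(flat, k)
                y0_, y1_ = max(0, vy - 1), min(k, vy + 2)
                x0_, x1_ = max(0, vx - 1), min(k, vx + 2)
                win = pk[q, y0_:y1_, x0_:x1_]
                wsum = win.sum()
                gy, gx = np.mgrid[y0_:y1_, x0_:x1_]
                u[q] = (win * gx).sum() / wsum
                v[q] = (win * gy).sum() / wsum
            xs = roi[0] + (u + 0.5) / k * (roi[2] - roi[0])
            ys = roi[1] + (v + 0.5) / k * (roi[3] - roi[1])
            xs = np.clip(xs, 0, size - 1)
            ys = np.clip(ys, 0, size - 1)
            try:
                box = BoundingBox(*(float(v_) for v_ in refined))
            except ValueError:
                box = BoundingBox(*(float(v_) for v_ in roi))
            out.append(
                Detection(
                    box=box,
                    score=score,
                    keypoints=KeypointSet.from_array(np.stack([xs, ys], axis=1)),
                )
            )
        return out

    # -- persistence --------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{idx}": p.value for idx, p in enumerate(self.params())}
        np.savez(path, _config=np.array([repr(self.cfg.to_dict())]), **arrays)

    @classmethod
    def load(cls, path) -> "KeypointDetector":
        import ast

        state = np.load(path, allow_pickle=False)
        cfg = DetectorConfig(**ast.literal_eval(str(state["_config"][0])))
        model = cls(cfg)
        params = model.params()
        model.load_state_dict([state[f"p{idx}"] for idx in range(len(params))])
        return model

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(
            self.params(),
            lr=lr,
            betas=(self.cfg.beta1, self.cfg.beta2),
            weight_decay=self.cfg.weight_decay,
        )
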