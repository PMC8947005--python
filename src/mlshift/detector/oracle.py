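"""Noise-injection oracle detector.

A test double that stands in for a trained model: it returns the
ground-truth landmarks of each annotated slice, optionally perturbed by
i.i.d. Gaussian noise per coordinate (``sigma_px``) and with each slice
dropped with probability ``dropout_rate``. It isolates the downstream
geometry and evaluation machinery from detector training, and makes the
cohort-level noise response analytically predictable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..geometry import KeypointSet, keypoints_to_bbox
from ..io import AnnotationRecord
from .model import Detection

__all__ = ["oracle_detector", "OracleDetector"]


def oracle_detector(
    ground_truth: Sequence[AnnotationRecord],
    sigma_px: float = 0.0,
    dropout_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> dict[int, Optional[Detection]]:
    """Per-slice detections from ground-truth annotations of one scan.

    Deterministic under ``rng``; with ``sigma_px = 0`` and
    ``dropout_rate = 0`` the output reproduces the annotations exactly
    (score 1.0). Noisy coordinates are clipped at 0 so the keypoint-set
    invariants keep holding.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = rng or np.random.default_rng(0)
    out: dict[int, Optional[Detection]] = {}
    for rec in ground_truth:
        if dropout_rate > 0 and rng.random() < dropout_rate:
            out[rec.slice_index] = None
            continue
        arr = rec.keypoints.as_array()
        if sigma_px > 0:
            arr = arr + rng.normal(0.0, sigma_px, arr.shape)
        arr = np.clip(arr, 0.0, None)
        kp = KeypointSet.from_array(arr)
        out[rec.slice_index] = Detection(
            box=keypoints_to_bbox(kp), score=1.0, keypoints=kp
        )
    return out


class OracleDetector:
    """Stateful wrapper so the oracle can be passed wherever a trained
    model is expected (keyed by scan_id)."""

    def __init__(
        self,
        annotations: Sequence[AnnotationRecord],
        sigma_px: float = 0.0,
        dropout_rate: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ):
        self.by_scan: dict[str, list[AnnotationRecord]] = {}
        for rec in annotations:
            self.by_scan.setdefault(rec.scan_id, []).append(rec)
        self.sigma_px = sigma_px
        self.dropout_rate = dropout_rate
        self.rng = rng or np.random.default_rng(0)

    def detect_scan(self, scan_id: str) -> dict[int, Optional[Detection]]:
        return oracle_detector(
            self.by_scan.get(scan_id, []), self.sigma_px, self.dropout_rate, self.rng
        )
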