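"""End-to-end measurement: volume in, per-scan midline shift out."""

from __future__ import annotations

from typing import Optional, Union

from ..geometry import MLSResult, aggregate_scan, compute_mls_slice
from ..io import CTVolume
from ..preprocess import DEFAULT_WINDOWS, preprocess_volume
from .model import KeypointDetector
from .oracle import OracleDetector
from .train import predict_keypoints

__all__ = ["run_pipeline"]


def run_pipeline(
    vol: CTVolume,
    model: Union[KeypointDetector, OracleDetector],
    windows=DEFAULT_WINDOWS,
    score_threshold: Optional[float] = None,
) -> MLSResult:
    """Measure the midline shift of one scan.

    With a trained :class:`KeypointDetector` the volume is preprocessed
    (resize, slice stacking, windowing), the detector is run per slice,
    detected keypoints are mapped back to native pixel space and the
    per-slice MLS values are aggregated to their maximum. With an
    :class:`OracleDetector` the (possibly noise-injected) ground-truth
    landmarks are used directly — the oracle never looks at pixels, so the
    preprocessing stage is bypassed.

    Slices with no detection are excluded; if nothing is detected the
    result has ``defined=False`` and is returned without error.
    """
    spacing = vol.in_plane_spacing
    if isinstance(model, OracleDetector):
        detections = model.detect_scan(vol.scan_id)
    else:
        inputs = preprocess_volume(vol, windows)
        detections = predict_keypoints(
            model, inputs, score_threshold, native_size=vol.slice_shape
        )
    per_slice = [
        (i, compute_mls_slice(det.keypoints, spacing))
        for i, det in sorted(detections.items())
        if det is not None
    ]
    return aggregate_scan(per_slice, vol.scan_id, source="prediction")
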