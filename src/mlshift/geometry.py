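"""Keypoint geometry of the midline shift.

Midline shift (MLS) is the lateral displacement of the septum pellucidum from
the ideal midline defined by the falx cerebri, measured in millimetres on an
axial slice. Four named landmarks define the measurement on one slice:

* ``falx_anterior`` / ``falx_posterior`` — the anterior and posterior
  attachments of the falx, spanning the ideal midline;
* ``septum_anterior`` / ``septum_posterior`` — the anterior and posterior ends
  of the septum pellucidum.

The per-slice MLS is the distance between the midpoint of the falx line and
the midpoint of the septum segment, computed in physical (mm) space; the
per-scan MLS is the maximum over slices.

Coordinates are 0-based pixel coordinates with ``x`` = column index and
``y`` = row index, origin at the top-left of the axial image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "KEYPOINT_NAMES",
    "KeypointSet",
    "BoundingBox",
    "MLSResult",
    "compute_mls_slice",
    "keypoints_to_bbox",
    "aggregate_scan",
    "rescale_keypoints",
]

#: Canonical landmark names, in storage order.
KEYPOINT_NAMES = (
    "falx_anterior",
    "falx_posterior",
    "septum_anterior",
    "septum_posterior",
)


@dataclass(frozen=True)
class KeypointSet:
    """The four landmarks of one axial slice, in pixel coordinates (x, y)."""

    falx_anterior: tuple[float, float]
    falx_posterior: tuple[float, float]
    septum_anterior: tuple[float, float]
    septum_posterior: tuple[float, float]

    def __post_init__(self) -> None:
        for name in KEYPOINT_NAMES:
            x, y = getattr(self, name)
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"keypoint {name!r} has non-finite coordinates")
            if x < 0 or y < 0:
                raise ValueError(f"keypoint {name!r} has negative coordinates")
        if self.falx_anterior == self.falx_posterior:
            raise ValueError("degenerate falx: anterior and posterior ends coincide")

    def as_array(self) -> np.ndarray:
        """Return the landmarks as a (4, 2) float array in canonical order."""
        return np.array([getattr(self, n) for n in KEYPOINT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray | Sequence[Sequence[float]]) -> "KeypointSet":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4, 2):
            raise ValueError(f"expected shape (4, 2), got {a.shape}")
        return cls(*(tuple(float(v) for v in row) for row in a))

    def to_dict(self) -> dict[str, list[float]]:
        return {n: [float(c) for c in getattr(self, n)] for n in KEYPOINT_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "KeypointSet":
        unknown = set(d) - set(KEYPOINT_NAMES)
        if unknown:
            raise ValueError(
                f"unknown keypoint name(s) {sorted(unknown)}; "
                f"legal names are {list(KEYPOINT_NAMES)}"
            )
        missing = set(KEYPOINT_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing keypoint(s) {sorted(missing)}")
        return cls(**{n: (float(d[n][0]), float(d[n][1])) for n in KEYPOINT_NAMES})


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, ``x_min < x_max``, ``y_min < y_max``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("bounding box must have positive width and height")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains(self, point: tuple[float, float]) -> bool:
        x, y = point
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass
class MLSResult:
    """Per-slice and per-scan midline-shift measurements for one scan.

    ``scan_mls_mm`` is the maximum of the per-slice values (ties broken by the
    lowest slice index). When no slice carries a measurement the result is
    flagged ``defined=False`` and ``scan_mls_mm`` is NaN.
    """

    scan_id: str
    per_slice: list[tuple[int, float]] = field(default_factory=list)
    scan_mls_mm: float = float("nan")
    argmax_slice_index: int | None = None
    source: Literal["annotation", "prediction"] = "annotation"
    defined: bool = False


def compute_mls_slice(
    k: KeypointSet,
    spacing: tuple[float, float],
    mode: Literal["midpoint_distance", "perpendicular_to_falx"] = "midpoint_distance",
) -> float:
    """Midline shift of one slice, in millimetres.

    Parameters
    ----------
    k
        The four landmarks in pixel coordinates.
    spacing
        ``(row_mm, col_mm)`` pixel spacing; each displacement axis is scaled
        by its spacing before the norm, so anisotropic pixels are handled.
    mode
        ``midpoint_distance`` (default): Euclidean distance between the
        falx-line midpoint and the septum midpoint.
        ``perpendicular_to_falx``: the component of that displacement
        perpendicular to the falx line (an alternative reading of the
        measurement geometry, provided for comparison).
    """
    row_mm, col_mm = float(spacing[0]), float(spacing[1])
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError("spacing components must be strictly positive")
    pts = k.as_array()
    # mm-space coordinates: x (column) scaled by col_mm, y (row) by row_mm
    mm = pts * np.array([col_mm, row_mm])
    falx_mid = (mm[0] + mm[1]) / 2.0
    septum_mid = (mm[2] + mm[3]) / 2.0
    disp = septum_mid - falx_mid
    if mode == "midpoint_distance":
        return float(np.hypot(disp[0], disp[1]))
    if mode == "perpendicular_to_falx":
        falx_vec = mm[1] - mm[0]
        norm = float(np.hypot(falx_vec[0], falx_vec[1]))
        # falx non-degeneracy is a KeypointSet invariant, norm > 0
        perp = disp - falx_vec * (disp @ falx_vec) / norm**2
        return float(np.hypot(perp[0], perp[1]))
    raise ValueError(f"unknown mls mode {mode!r}")


def keypoints_to_bbox(
    k: KeypointSet,
    image_size: tuple[int, int] | None = None,
    scale: float = 1.2,
    aspect: float = 0.8,
) -> BoundingBox:
    """Ground-truth detection box derived from the falx line.

    The box is axis-aligned and centred on the falx midpoint; its height is
    ``scale`` (default 1.2) times the falx-line length and its width is
    ``aspect`` (default 0.8) times the height. With ``scale > 1`` both falx
    endpoints are contained. When ``image_size = (height, width)`` is given
    the box is clipped to the image bounds (which may change the aspect
    ratio of a box near the border).
    """
    pts = k.as_array()
    falx_len = float(np.linalg.norm(pts[1] - pts[0]))
    cx, cy = (pts[0] + pts[1]) / 2.0
    height = scale * falx_len
    width = aspect * height
    box = (cx - width / 2, cy - height / 2, cx + width / 2, cy + height / 2)
    if image_size is not None:
        h, w = image_size
        box = (
            max(box[0], 0.0),
            max(box[1], 0.0),
            min(box[2], float(w - 1)),
            min(box[3], float(h - 1)),
        )
    return BoundingBox(*box)


def aggregate_scan(
    per_slice: Sequence[tuple[int, float]],
    scan_id: str,
    source: Literal["annotation", "prediction"] = "annotation",
) -> MLSResult:
    """Per-scan MLS: the greatest per-slice MLS, with its slice index.

    Ties break to the lowest slice index. An empty input yields a result with
    ``defined=False`` and NaN millimetres (a scan where no slice produced a
    measurement is still reported, it just carries no value).
    """
    per_slice = [(int(i), float(v)) for i, v in per_slice]
    for i, v in per_slice:
        if v < 0:
            raise ValueError(f"negative MLS {v} at slice {i}")
    if not per_slice:
        return MLSResult(scan_id=scan_id, source=source, defined=False)
    ordered = sorted(per_slice, key=lambda t: t[0])
    best_idx, best_val = max(ordered, key=lambda t: (t[1], -t[0]))
    return MLSResult(
        scan_id=scan_id,
        per_slice=ordered,
        scan_mls_mm=best_val,
        argmax_slice_index=best_idx,
        source=source,
        defined=True,
    )


def rescale_keypoints(
    k: KeypointSet,
    from_size: tuple[int, int],
    to_size: tuple[int, int],
) -> KeypointSet:
    """Map keypoints between image resolutions (``(height, width)`` sizes).

    Coordinates scale per-axis by ``to/from``; the operation is invertible up
    to floating-point rounding. Used to keep annotations consistent across
    the model-input resize.
    """
    fh, fw = from_size
    th, tw = to_size
    if min(fh, fw, th, tw) <= 0:
        raise ValueError("image sizes must be positive")
    sx, sy = tw / fw, th / fh
    return KeypointSet.from_array(k.as_array() * np.array([sx, sy]))
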