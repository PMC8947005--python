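"""CT preprocessing: resize, adjacent-slice stacking, windowing, normalisation.

Each axial slice becomes one 3-channel model input: the three spatially
adjacent slices (previous, current, next — edge slices replicated) are
resized to 512x512 and each channel is passed through its own intensity
window, mapping the HU range [level - width/2, level + width/2] linearly
onto [0, 1] with clipping outside. The default windows are a subdural-type
window (level 80, width 200), a soft-tissue window (40, 380) and a bone
window (600, 2800), so soft tissue, fresh blood and bone each land in the
informative range of at least one channel.

Windowing is applied after the resize, on interpolated HU values; the resize
preserves the physical field of view, so the effective pixel spacing after
resizing to ``target`` pixels is ``native_spacing * native_size / target``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import CTVolume

__all__ = [
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "ModelInput",
    "apply_window",
    "stack_slices",
    "resize_slice",
    "preprocess_volume",
]


@dataclass(frozen=True)
class WindowSpec:
    """An intensity window, ``level`` ± ``width``/2 HU."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def low(self) -> float:
        return self.level - self.width / 2.0

    @property
    def high(self) -> float:
        return self.level + self.width / 2.0


#: Default (level, width) windows: subdural-type, soft tissue, bone.
DEFAULT_WINDOWS = (
    WindowSpec(80, 200),
    WindowSpec(40, 380),
    WindowSpec(600, 2800),
)


@dataclass
class ModelInput:
    """One model-ready slice: 3 windowed channels, 512x512, values in [0, 1]."""

    pixels: np.ndarray  # (3, target, target) float32
    scan_id: str
    center_slice_index: int
    effective_spacing: tuple[float, float]  # (row_mm, col_mm) after resize


def apply_window(slice_hu: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Map HU linearly from [w.low, w.high] onto [0, 1], clipping outside."""
    out = (np.asarray(slice_hu, dtype=np.float64) - w.low) / w.width
    return np.clip(out, 0.0, 1.0)


def stack_slices(vol: CTVolume, i: int) -> np.ndarray:
    """Three adjacent raw-HU slices ``(i-1, i, i+1)`` as a (3, H, W) array.

    At the volume boundaries the edge slice is replicated, so slice 0 yields
    channels (0, 0, 1) and the last slice (n-2, n-1, n-1).
    """
    n = vol.n_slices
    if not 0 <= i < n:
        raise IndexError(f"slice index {i} out of range for {n}-slice volume")
    idx = (max(i - 1, 0), i, min(i + 1, n - 1))
    return np.stack([vol.voxels[j] for j in idx], axis=0)


def resize_slice(
    slice_2d: np.ndarray,
    native_spacing: tuple[float, float] = (1.0, 1.0),
    target: int = 512,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Bilinear resize to ``target`` x ``target``; returns the resized slice
    and the effective (row_mm, col_mm) spacing that preserves the physical
    field of view."""
    arr = np.asarray(slice_2d, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D slice")
    h, w = arr.shape
    eff = (native_spacing[0] * h / target, native_spacing[1] * w / target)
    if (h, w) == (target, target):
        return arr.copy(), eff
    out = _sk_resize(arr, (target, target), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out, eff


def preprocess_volume(
    vol: CTVolume,
    windows: tuple[WindowSpec, WindowSpec, WindowSpec] = DEFAULT_WINDOWS,
    target: int = 512,
) -> list[ModelInput]:
    """Full per-slice preprocessing of a volume.

    For every slice index ``i``, channel ``k`` is window ``k`` applied to the
    resized adjacent slice ``k`` of the (i-1, i, i+1) stack. Output order
    follows slice order; one ModelInput per slice regardless of content.
    """
    if len(windows) != 3:
        raise ValueError(f"exactly 3 windows required, got {len(windows)}")
    row_mm, col_mm = vol.in_plane_spacing
    inputs: list[ModelInput] = []
    # resize each native slice once, then assemble the 3-slice stacks
    resized = np.empty((vol.n_slices, target, target), dtype=np.float64)
    for j in range(vol.n_slices):
        resized[j], eff = resize_slice(vol.voxels[j], (row_mm, col_mm), target)
    n = vol.n_slices
    for i in range(n):
        idx = (max(i - 1, 0), i, min(i + 1, n - 1))
        channels = [apply_window(resized[j], w) for j, w in zip(idx, windows)]
        inputs.append(
            ModelInput(
                pixels=np.stack(channels, axis=0).astype(np.float32),
                scan_id=vol.scan_id,
                center_slice_index=i,
                effective_spacing=eff,
            )
        )
    return inputs
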