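"""Training-time augmentations for slice images with landmark annotations.

Four augmentations, each gated by a config flag and applied independently
with a fixed probability: sagittal flip (x-mirror; landmark identities are
preserved — the anterior falx stays the anterior falx), a small random
affine (rotation, isotropic scale and translation applied identically to
image and landmarks), random rectangular erasing (image only; landmarks are
never relocated), and simplified metal-streak artifacts added in the
normalised intensity domain. An affine draw that would push any landmark
out of bounds is resampled up to 10 times, then the affine is skipped.

All augmentations are the identity when their flags are off, and are
deterministic under the supplied random generator.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage

from ..geometry import KeypointSet
from ..phantom import simulate_metal_streaks
from .model import DetectorConfig

__all__ = ["augment_sample"]

_P_FLIP = 0.5
_P_AFFINE = 0.5
_P_ERASE = 0.3
_P_STREAK = 0.3


def _apply_affine(image, kp_arr, rng, size):
    """Random rotation/scale/translation; returns None if landmarks leave
    the image after 10 attempts."""
    for _ in range(10):
        angle = rng.uniform(-8.0, 8.0) * math.pi / 180.0
        scale = rng.uniform(0.95, 1.05)
        tx, ty = rng.uniform(-0.05, 0.05, 2) * size
        c = (size - 1) / 2.0
        cos, sin = math.cos(angle) * scale, math.sin(angle) * scale
        # forward map: p' = R (p - c) + c + t
        mat = np.array([[cos, -sin], [sin, cos]])
        if kp_arr is not None:
            new_kp = (kp_arr - c) @ mat.T + c + np.array([tx, ty])
            if np.any(new_kp < 0) or np.any(new_kp > size - 1):
                continue
        else:
            new_kp = None
        # ndimage pulls output pixels from input: needs the inverse map,
        # in (row, col) = (y, x) order
        inv = np.linalg.inv(mat)
        inv_rc = inv[::-1, ::-1]  # swap x/y axes on both sides
        c_vec = np.array([c, c])
        offset_xy = c_vec - inv @ (c_vec + np.array([tx, ty]))
        offset_rc = offset_xy[::-1]
        warped = np.stack(
            [
                ndimage.affine_transform(
                    ch, inv_rc, offset=offset_rc, order=1, mode="constant", cval=0.0
                )
                for ch in image
            ]
        )
        return warped.astype(image.dtype), new_kp
    return None


def augment_sample(
    image: np.ndarray,
    keypoints: Optional[KeypointSet],
    cfg: DetectorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Optional[KeypointSet]]:
    """Randomly augment one (3, S, S) image and its landmarks (or None)."""
    size = image.shape[-1]
    kp_arr = keypoints.as_array() if keypoints is not None else None

    if cfg.augment_flip_sagittal and rng.random() < _P_FLIP:
        image = image[:, :, ::-1].copy()
        if kp_arr is not None:
            kp_arr = kp_arr.copy()
            kp_arr[:, 0] = (size - 1) - kp_arr[:, 0]

    if cfg.augment_affine and rng.random() < _P_AFFINE:
        result = _apply_affine(image, kp_arr, rng, size)
        if result is not None:
            image, kp_arr = result

    if cfg.augment_erasing and rng.random() < _P_ERASE:
        eh = int(rng.uniform(0.1, 0.25) * size)
        ew = int(rng.uniform(0.1, 0.25) * size)
        y0 = int(rng.integers(0, size - eh))
        x0 = int(rng.integers(0, size - ew))
        image = image.copy()
        image[:, y0 : y0 + eh, x0 : x0 + ew] = 0.0

    if cfg.augment_metal_streaks and rng.random() < _P_STREAK:
        n_streaks = int(rng.integers(2, 6))
        amp = float(rng.uniform(0.1, 0.4))
        image = np.stack(
            [
                np.clip(simulate_metal_streaks(ch, n_streaks, amp, rng), 0.0, 1.0)
                for ch in image
            ]
        ).astype(image.dtype)

    kps = KeypointSet.from_array(kp_arr) if kp_arr is not None else None
    return image, kps
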