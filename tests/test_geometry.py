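"""Keypoint-MLS geometry: distance formula, bounding box, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlshift.geometry import (
    KeypointSet,
    aggregate_scan,
    compute_mls_slice,
    keypoints_to_bbox,
    rescale_keypoints,
)


def mm_distance_oracle(kp: KeypointSet, spacing):
    """Independent mm-space midpoint-distance computation (plain loops)."""
    row_mm, col_mm = spacing
    pts = {n: getattr(kp, n) for n in
           ("falx_anterior", "falx_posterior", "septum_anterior", "septum_posterior")}
    fx = (pts["falx_anterior"][0] + pts["falx_posterior"][0]) / 2 * col_mm
    fy = (pts["falx_anterior"][1] + pts["falx_posterior"][1]) / 2 * row_mm
    sx = (pts["septum_anterior"][0] + pts["septum_posterior"][0]) / 2 * col_mm
    sy = (pts["septum_anterior"][1] + pts["septum_posterior"][1]) / 2 * row_mm
    return math.sqrt((fx - sx) ** 2 + (fy - sy) ** 2)


def random_keypoints(rng, size=512):
    while True:
        pts = rng.uniform(1, size - 2, (4, 2))
        if not np.allclose(pts[0], pts[1]):
            return KeypointSet.from_array(pts)


def random_plausible_keypoints(rng, size=512):
    """Anatomically plausible configuration: falx within 30 degrees of
    vertical (anterior at smaller y), septum near the falx midline."""
    cx = rng.uniform(0.35, 0.65) * size
    cy = rng.uniform(0.35, 0.65) * size
    half = rng.uniform(0.15, 0.3) * size
    theta = rng.uniform(-np.pi / 6, np.pi / 6)
    dx, dy = half * np.sin(theta), half * np.cos(theta)
    shift = rng.uniform(-0.05, 0.05) * size
    sep_half = rng.uniform(0.03, 0.08) * size
    return KeypointSet(
        falx_anterior=(cx - dx, cy - dy),
        falx_posterior=(cx + dx, cy + dy),
        septum_anterior=(cx + shift, cy - sep_half),
        septum_posterior=(cx + shift, cy + sep_half),
    )


class TestComputeMLS:
    def test_coincident_midpoints_give_zero(self):
        kp = KeypointSet((100, 50), (100, 350), (98, 190), (102, 210))
        assert compute_mls_slice(kp, (0.7, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_geometry_example(self):
        # falx midpoint (256,250), septum midpoint (262,250): 6 px * 0.5 mm
        kp = KeypointSet((256, 100), (256, 400), (260, 240), (264, 260))
        assert compute_mls_slice(kp, (0.5, 0.5)) == pytest.approx(3.0, abs=1e-12)

    def test_matches_mm_space_oracle_with_anisotropic_spacing(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            kp = random_keypoints(rng)
            spacing = tuple(rng.uniform(0.2, 2.5, 2))
            assert compute_mls_slice(kp, spacing) == pytest.approx(
                mm_distance_oracle(kp, spacing), abs=1e-9
            )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        kp = random_keypoints(rng)
        shifted = KeypointSet.from_array(kp.as_array() + [13.5, 7.25])
        assert compute_mls_slice(kp, (0.6, 0.8)) == pytest.approx(
            compute_mls_slice(shifted, (0.6, 0.8)), abs=1e-9
        )

    def test_rotation_invariance_with_isotropic_spacing(self):
        rng = np.random.default_rng(2)
        kp = random_keypoints(rng, size=200)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        rotated = KeypointSet.from_array(
            (kp.as_array() - 100) @ rot.T + 300  # keep coordinates positive
        )
        assert compute_mls_slice(kp, (0.5, 0.5)) == pytest.approx(
            compute_mls_slice(rotated, (0.5, 0.5)), abs=1e-9
        )

    def test_doubling_spacing_doubles_mls(self):
        rng = np.random.default_rng(3)
        kp = random_keypoints(rng)
        assert compute_mls_slice(kp, (1.2, 0.8)) * 2 == pytest.approx(
            compute_mls_slice(kp, (2.4, 1.6)), rel=1e-12
        )

    def test_symmetric_perpendicular_shift_recovers_displacement(self):
        # septum endpoints both displaced d mm perpendicular to a vertical falx
        d_mm, col_mm = 4.2, 0.6
        d_px = d_mm / col_mm
        kp = KeypointSet((256, 100), (256, 400), (256 + d_px, 230), (256 + d_px, 270))
        assert compute_mls_slice(kp, (0.5, col_mm)) == pytest.approx(d_mm, abs=1e-9)

    def test_perpendicular_mode_drops_along_falx_component(self):
        # septum midpoint offset both along (y) and across (x) a vertical falx
        kp = KeypointSet((256, 100), (256, 400), (266, 270), (266, 310))
        full = compute_mls_slice(kp, (0.5, 0.5))
        perp = compute_mls_slice(kp, (0.5, 0.5), mode="perpendicular_to_falx")
        assert perp == pytest.approx(10 * 0.5, abs=1e-9)
        assert perp < full

    def test_degenerate_falx_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            KeypointSet((10, 10), (10, 10), (20, 20), (30, 30))


class TestBoundingBox:
    def test_vertical_falx_arithmetic(self):
        kp = KeypointSet((256, 100), (256, 400), (260, 240), (264, 260))
        box = keypoints_to_bbox(kp)
        assert box.height == pytest.approx(360.0)
        assert box.width == pytest.approx(288.0)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == pytest.approx(
            (112.0, 70.0, 400.0, 430.0)
        )

    def test_falx_endpoints_contained_and_aspect_fixed(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            kp = random_plausible_keypoints(rng)
            box = keypoints_to_bbox(kp)
            assert box.contains(kp.falx_anterior)
            assert box.contains(kp.falx_posterior)
            assert box.width / box.height == pytest.approx(0.8, abs=1e-6)
            assert box.height == pytest.approx(
                1.2 * np.linalg.norm(np.subtract(kp.falx_posterior, kp.falx_anterior))
            )

    def test_clipping_to_image_bounds(self):
        kp = KeypointSet((20, 10), (20, 500), (30, 240), (30, 260))
        box = keypoints_to_bbox(kp, image_size=(512, 512))
        assert box.x_min >= 0 and box.y_min >= 0
        assert box.x_max <= 511 and box.y_max <= 511


class TestAggregate:
    def test_max_and_argmax(self):
        res = aggregate_scan([(3, 1.2), (4, 3.4), (5, 0.5)], "s")
        assert res.scan_mls_mm == 3.4
        assert res.argmax_slice_index == 4
        assert res.defined

    def test_empty_input_undefined(self):
        res = aggregate_scan([], "s")
        assert not res.defined
        assert math.isnan(res.scan_mls_mm)
        assert res.argmax_slice_index is None

    def test_tie_breaks_to_lowest_slice(self):
        assert aggregate_scan([(2, 2.0), (1, 2.0)], "s").argmax_slice_index == 1

    def test_negative_mls_rejected(self):
        with pytest.raises(ValueError):
            aggregate_scan([(0, -0.1)], "s")

    @given(st.lists(st.tuples(st.integers(0, 30),
                              st.floats(0, 30, allow_nan=False)), min_size=1))
    @settings(max_examples=50, deadline=None)
    def test_adding_larger_slice_never_decreases_scan_mls(self, per_slice):
        per_slice = list({i: v for i, v in per_slice}.items())
        base = aggregate_scan(per_slice, "s").scan_mls_mm
        bigger = aggregate_scan(per_slice + [(99, base + 1.0)], "s").scan_mls_mm
        assert bigger >= base


class TestRescale:
    def test_identity_and_doubling(self):
        kp = KeypointSet((10, 20), (30, 40), (50, 60), (70, 80))
        same = rescale_keypoints(kp, (256, 256), (256, 256))
        assert np.allclose(same.as_array(), kp.as_array())
        doubled = rescale_keypoints(kp, (256, 256), (512, 512))
        assert np.allclose(doubled.as_array(), kp.as_array() * 2)

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        kp = random_keypoints(rng, size=333)
        back = rescale_keypoints(
            rescale_keypoints(kp, (333, 333), (512, 512)), (512, 512), (333, 333)
        )
        assert np.allclose(back.as_array(), kp.as_array(), atol=1e-9)
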