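"""Gradient-orientation features: encoding, windows, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msinc import (
    ImageStack,
    build_feature_matrix,
    compute_orientation,
    extract_window_features,
)


def ramp(H=9, W=9, axis=1):
    """I(x, y) = x (axis=1, horizontal) or y (axis=0, vertical)."""
    return np.add.outer(
        np.arange(H) * (axis == 0), np.arange(W) * (axis == 1)
    ).astype(float)


class TestComputeOrientation:
    def test_horizontal_ramp_points_along_x(self):
        f = compute_orientation(ramp(axis=1))
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(f.cos[inner], 1.0)
        assert np.allclose(f.sin[inner], 0.0)
        assert f.valid[inner].all()

    def test_vertical_ramp_points_along_y(self):
        f = compute_orientation(ramp(axis=0))
        inner = (slice(1, -1), slice(1, -1))
        assert np.allclose(f.cos[inner], 0.0)
        assert np.allclose(f.sin[inner], 1.0)

    def test_constant_image_all_invalid_zero_encoded(self):
        f = compute_orientation(np.full((8, 8), 3.7))
        assert not f.valid.any()
        assert (f.cos == 0).all() and (f.sin == 0).all()

    def test_unit_norm_at_valid_pixels(self, rng):
        f = compute_orientation(rng.random((16, 16)))
        norms = f.cos[f.valid] ** 2 + f.sin[f.valid] ** 2
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        img = rng.random((12, 12))
        f1, f2 = compute_orientation(img), compute_orientation(1234.5 * img)
        assert np.allclose(f1.cos[f1.valid], f2.cos[f1.valid], atol=1e-9)
        assert np.allclose(f1.sin[f1.valid], f2.sin[f1.valid], atol=1e-9)

    def test_rotation_by_90_permutes_channels(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.standard_normal((30, 30)), 3)
        f, g = compute_orientation(img), compute_orientation(np.rot90(img))
        inner = (slice(2, -2), slice(2, -2))
        # np.rot90 maps the unit direction (cos, sin) -> (sin, -cos)
        assert np.allclose(g.cos[inner], np.rot90(f.sin)[inner], atol=1e-9)
        assert np.allclose(g.sin[inner], -np.rot90(f.cos)[inner], atol=1e-9)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_rejects_non_finite(self, bad):
        img = np.ones((5, 5))
        img[2, 2] = bad
        with pytest.raises(ValueError, match="finite"):
            compute_orientation(img)

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            compute_orientation(np.ones((2, 5)))


class TestWindowFeatures:
    def test_window7_gives_98_features(self, rng):
        f = compute_orientation(rng.random((10, 10)))
        assert extract_window_features(f, 7).shape == (10, 10, 98)

    def test_constant_field_repeats_pair(self):
        f = compute_orientation(ramp(axis=1))
        feats = extract_window_features(f, 3)
        expected = np.tile([1.0, 0.0], 9)
        inner = feats[2:-2, 2:-2]
        assert np.allclose(inner, expected)

    def test_corner_pixel_fully_defined(self, rng):
        f = compute_orientation(rng.random((9, 9)))
        feats = extract_window_features(f, 3)
        assert np.isfinite(feats[0, 0]).all()
        assert feats[0, 0].shape == (18,)

    def test_rejects_even_window(self, rng):
        f = compute_orientation(rng.random((9, 9)))
        with pytest.raises(ValueError, match="odd"):
            extract_window_features(f, 4)


class TestFeatureMatrix:
    def make_stack(self, rng, s=2, H=9, W=9):
        return ImageStack(bands=[rng.random((H, W)) for _ in range(s)])

    def test_shape_and_blocks(self, rng):
        fm = build_feature_matrix(self.make_stack(rng), window=3)
        assert fm.values.shape == (36, 81)
        assert fm.block_bounds == [(0, 18), (18, 36)]
        assert (fm.d_js == 18).all()

    def test_deterministic(self, rng):
        stack = self.make_stack(rng)
        a = build_feature_matrix(stack, window=3)
        b = build_feature_matrix(stack, window=3)
        assert np.array_equal(a.values, b.values)

    def test_rows_centered(self, rng):
        fm = build_feature_matrix(self.make_stack(rng), window=3)
        assert np.allclose(fm.values.sum(axis=1), 0.0, atol=1e-9)

    def test_mask_selects_columns(self, rng):
        stack = self.make_stack(rng)
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:5, 3:6] = True
        fm = build_feature_matrix(stack, window=3, mask=mask)
        assert fm.n == 9
        assert np.array_equal(fm.pixel_index, np.flatnonzero(mask.ravel()))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="zero pixels"):
            build_feature_matrix(
                self.make_stack(rng), window=3, mask=np.zeros((9, 9), bool)
            )

    def test_single_band_stack_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            ImageStack(bands=[rng.random((9, 9))])

    @given(
        s=st.integers(2, 4),
        w=st.sampled_from([3, 5, 7]),
        H=st.integers(9, 14),
        W=st.integers(9, 14),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dimension_bookkeeping(self, s, w, H, W):
        """d = s * 2 w^2 and n = H * W for any stack geometry."""
        gen = np.random.default_rng(abs(hash((s, w, H, W))) % 2**31)
        stack = ImageStack(bands=[gen.random((H, W)) for _ in range(s)])
        fm = build_feature_matrix(stack, window=w)
        assert fm.d == s * 2 * w * w
        assert fm.n == H * W
        assert fm.s == s
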