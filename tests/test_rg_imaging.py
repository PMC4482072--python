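"""Dual-gain fusion, background correction, ratio imaging, raw format."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from frit.rg_imaging import (
    SENTINEL,
    RatioImage,
    apply_cellmask,
    background_correct,
    compute_ratio_image,
    estimate_background,
    fuse_dual_gain,
    read_raw,
    render_color,
    write_raw,
)


class TestFuseDualGain:
    def test_identity_when_unsaturated(self):
        rng = np.random.default_rng(0)
        high = rng.uniform(0, 100, (32, 32))
        fused, invalid = fuse_dual_gain(high / 10, high, saturation_level=255)
        np.testing.assert_array_equal(fused, high)
        assert not invalid.any()

    def test_hdr_oracle_exact_reconstruction(self):
        """A synthetic truth spanning the saturation point is recovered exactly."""
        truth = np.linspace(1, 2000, 64 * 64).reshape(64, 64)
        sat = 255.0
        low = truth / 10
        high = np.minimum(truth, sat)
        fused, invalid = fuse_dual_gain(low, high, saturation_level=sat)
        np.testing.assert_allclose(fused, truth, rtol=1e-12)
        assert not invalid.any()

    def test_double_saturation_flagged(self):
        low = np.full((4, 4), 255.0)
        high = np.full((4, 4), 255.0)
        fused, invalid = fuse_dual_gain(low, high, saturation_level=255, gain_ratio=10)
        assert invalid.all()

    def test_error_without_estimable_ratio(self):
        # everything saturated at high gain, no ratio supplied
        low = np.full((4, 4), 30.0)
        high = np.full((4, 4), 255.0)
        with pytest.raises(ValueError):
            fuse_dual_gain(low, high, saturation_level=255)


class TestBackgroundCorrect:
    def test_scalar_subtraction(self):
        out = background_correct(np.full((3, 3), 10.0), 4.0)
        np.testing.assert_array_equal(out, np.full((3, 3), 6.0))

    def test_clamped_at_zero(self):
        out = background_correct(np.full((3, 3), 3.0), 5.0)
        np.testing.assert_array_equal(out, np.zeros((3, 3)))

    def test_auto_mode_of_sparse_image(self):
        """90 % zeros + bright objects: the histogram mode is 0, output unchanged."""
        rng = np.random.default_rng(1)
        img = np.zeros(1000)
        img[rng.choice(1000, 100, replace=False)] = rng.uniform(50, 200, 100)
        img = img.reshape(25, 40)
        assert estimate_background(img) == 0.0
        np.testing.assert_array_equal(background_correct(img, "auto"), img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            background_correct(np.zeros((3, 3)), np.zeros((2, 2)))


class TestComputeRatioImage:
    def test_pixel_values(self):
        donor = np.array([[100.0, 100.0, 2.0]])
        fret = np.array([[200.0, 30.0, 50.0]])
        ratio = compute_ratio_image(donor, fret, intensity_floor=5.0)
        assert ratio.values[0, 0] == 2.0
        assert ratio.values[0, 1] == pytest.approx(0.3)
        assert ratio.values[0, 2] == SENTINEL  # below donor floor

    def test_values_stored_unclamped(self):
        ratio = compute_ratio_image(np.array([[10.0]]), np.array([[50.0]]))
        assert ratio.values[0, 0] == 5.0  # above theta_max, not clamped


class TestRenderColor:
    def test_threshold_colors(self):
        ratio = RatioImage(np.array([[2.0, 0.3, 0.85, SENTINEL]]))
        rgb = render_color(ratio)
        assert tuple(rgb[0, 0]) == (255, 0, 0)      # intact: pure red
        assert tuple(rgb[0, 1]) == (0, 255, 0)      # degraded: pure green
        r, g, b = rgb[0, 2]
        assert b == 0 and 100 < r < 155 and 100 < g < 155  # midpoint olive
        assert tuple(rgb[0, 3]) == (0, 0, 0)        # background black

    def test_chain_preserves_foreground_count(self):
        """ratio -> color -> cellmask keeps exactly the non-background pixels."""
        rng = np.random.default_rng(2)
        donor = rng.uniform(0, 50, (32, 32))
        fret = rng.uniform(0, 50, (32, 32))
        ratio = compute_ratio_image(donor, fret, intensity_floor=10.0)
        color = render_color(ratio)
        masked = apply_cellmask(ratio.values, color)
        assert masked.foreground.sum() == ratio.foreground.sum()
        np.testing.assert_array_equal(masked.values, ratio.values)


class TestApplyCellmask:
    def test_zero_ratio_survives_masking(self):
        """An in-mask R/G of exactly 0 stays 0, distinguishable from background."""
        raw = np.array([[0.0, 0.73, 5.0]])
        color = np.array([[[0, 255, 0], [120, 135, 0], [0, 0, 0]]], dtype=np.uint8)
        masked = apply_cellmask(raw, color)
        assert masked.values[0, 0] == 0.0
        assert masked.values[0, 1] == 0.73
        assert masked.values[0, 2] == SENTINEL


class TestRawFormat:
    def test_expected_file_size(self, tmp_path):
        img = RatioImage(np.zeros((512, 512)))
        path = tmp_path / "frame.rg"
        write_raw(img, path)
        assert path.stat().st_size == 512 * 512 * 8 == 2_097_152
        read_raw(path)  # accepted at the default shape

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "bad.rg"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(ValueError):
            read_raw(path, shape=(512, 512))

    @settings(derandomize=True, max_examples=25)
    @given(
        values=hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=16),
            elements=st.one_of(
                st.just(SENTINEL),
                st.just(0.0),
                st.floats(min_value=0, max_value=1e6, allow_nan=False),
            ),
        )
    )
    def test_round_trip_bit_exact(self, values, tmp_path_factory):
        """Raw write/read is bit-identical, including 0 and sentinel pixels."""
        path = tmp_path_factory.mktemp("raw") / "x.rg"
        write_raw(RatioImage(values), path)
        back = read_raw(path, shape=values.shape)
        assert back.values.tobytes() == values.tobytes()
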