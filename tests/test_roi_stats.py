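"""Polygon rasterization, integrity distributions, compartment traces."""

import numpy as np
import pytest

from frit.calibration import integrity_from_rg
from frit.rg_imaging import SENTINEL, RatioImage
from frit.roi_stats import (
    RoiSet,
    compartment_traces,
    fraction_intact,
    integrity_distribution,
    rasterize_polygon,
)


def square(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@pytest.fixture
def roi():
    """10x10 cell square with a 4x4 nucleus inside, on a 12x12 image."""
    return RoiSet(cell=square(0.5, 0.5, 10.5, 10.5), nucleus=square(3.5, 3.5, 7.5, 7.5))


class TestRasterization:
    def test_square_pixel_centers(self):
        mask = rasterize_polygon(square(0.5, 0.5, 3.5, 3.5), (6, 6))
        assert mask.sum() == 9  # centers 1..3 in both axes
        assert mask[1:4, 1:4].all()

    def test_nucleus_outside_cell_rejected(self):
        bad = RoiSet(cell=square(0.5, 0.5, 4.5, 4.5), nucleus=square(5.5, 5.5, 8.5, 8.5))
        with pytest.raises(ValueError):
            bad.masks((12, 12))

    def test_mask_partition(self, roi):
        masks = roi.masks((12, 12))
        assert (masks["nucleus"] & ~masks["cell"]).sum() == 0
        assert masks["nucleus"].sum() + masks["cytosol"].sum() == masks["cell"].sum()

    def test_json_round_trip(self, roi, tmp_path):
        path = tmp_path / "roi.json"
        roi.to_json(path)
        back = RoiSet.from_json(path)
        np.testing.assert_allclose(back.cell, roi.cell)
        np.testing.assert_allclose(back.nucleus, roi.nucleus)


class TestIntegrityDistribution:
    def test_all_red(self, roi):
        ratio = RatioImage(np.full((12, 12), 2.0))
        dist = integrity_distribution(ratio, roi, "cell")
        assert (dist.frac_green, dist.frac_olive, dist.frac_red) == (0.0, 0.0, 1.0)

    def test_counted_fractions(self):
        """10 foreground pixels {0.4 x4, 0.8 x3, 1.5 x3} -> (0.4, 0.3, 0.3)."""
        values = np.full((1, 12), SENTINEL)
        values[0, :10] = [0.4] * 4 + [0.8] * 3 + [1.5] * 3
        ratio = RatioImage(values)
        mask = np.zeros((1, 12), dtype=bool)
        mask[0, :] = True
        dist = integrity_distribution(ratio, mask, "cell")
        assert dist.frac_green == pytest.approx(0.4)
        assert dist.frac_olive == pytest.approx(0.3)
        assert dist.frac_red == pytest.approx(0.3)

    @pytest.mark.parametrize("value, bin_name", [(0.5, "frac_olive"), (1.2, "frac_olive")])
    def test_boundary_values_assigned_inward(self, value, bin_name):
        ratio = RatioImage(np.full((2, 2), value))
        dist = integrity_distribution(ratio, np.ones((2, 2), dtype=bool), "cell")
        assert getattr(dist, bin_name) == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 2, (8, 8))
        mask = np.ones((8, 8), dtype=bool)
        d1 = integrity_distribution(RatioImage(values), mask, "cell")
        shuffled = values.ravel().copy()
        rng.shuffle(shuffled)
        d2 = integrity_distribution(RatioImage(shuffled.reshape(8, 8)), mask, "cell")
        assert (d1.frac_green, d1.frac_olive, d1.frac_red) == (
            d2.frac_green, d2.frac_olive, d2.frac_red,
        )
        assert d1.frac_green + d1.frac_olive + d1.frac_red == pytest.approx(1.0)

    def test_all_background_roi_rejected(self, roi):
        ratio = RatioImage(np.full((12, 12), SENTINEL))
        with pytest.raises(ValueError):
            integrity_distribution(ratio, roi, "cell")


class TestFractionIntact:
    def test_fully_intact(self, curve):
        ratio = RatioImage(np.full((4, 4), 5.0))
        mask = np.ones((4, 4), dtype=bool)
        assert fraction_intact(ratio, mask, curve) == pytest.approx(100.0)

    def test_half_intact_half_green_threshold(self, curve):
        """Half at R/G 5 (100 %), half at 0.5 (80 %) -> 90 %."""
        values = np.concatenate([np.full(8, 5.0), np.full(8, 0.5)]).reshape(4, 4)
        ratio = RatioImage(values)
        mask = np.ones((4, 4), dtype=bool)
        assert fraction_intact(ratio, mask, curve) == pytest.approx(90.0, abs=0.5)

    def test_green_threshold_is_80_percent(self, curve):
        ratio = RatioImage(np.full((4, 4), 0.5))
        mask = np.ones((4, 4), dtype=bool)
        assert fraction_intact(ratio, mask, curve) == pytest.approx(80.0, abs=1.0)

    def test_uniform_image_matches_pointwise_calibration(self, curve):
        for rg in (0.3, 0.8, 2.5):
            ratio = RatioImage(np.full((3, 3), rg))
            mask = np.ones((3, 3), dtype=bool)
            assert fraction_intact(ratio, mask, curve) == pytest.approx(
                integrity_from_rg(rg, curve), abs=1e-4
            )

    def test_monotone_in_pixel_values(self, curve):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 3, (5, 5))
        mask = np.ones((5, 5), dtype=bool)
        base = fraction_intact(RatioImage(values), mask, curve)
        bumped = values.copy()
        bumped[2, 2] += 0.5
        assert fraction_intact(RatioImage(bumped), mask, curve) >= base


class TestCompartmentTraces:
    def _stack(self, T, Z, fill):
        return np.full((T, Z, 12, 12), float(fill))

    def test_constant_region(self, roi):
        donor = self._stack(4, 2, 7.0)
        traces = compartment_traces(np.arange(4.0), donor, donor, donor * 0 + 1.0, roi)
        np.testing.assert_allclose(traces["cell"].mfi_donor, 7.0)

    def test_z_average(self, roi):
        donor = np.tile(np.arange(1.0, 6.0)[None, :, None, None], (1, 1, 12, 12))
        traces = compartment_traces([0.0], donor, donor, np.ones_like(donor), roi)
        assert traces["cell"].mfi_donor[0] == pytest.approx(3.0)  # mean of 1..5

    def test_step_input_detected_at_frame(self, roi):
        T = 100
        donor = np.zeros((T, 1, 12, 12))
        donor[50:] = 100.0
        traces = compartment_traces(np.arange(float(T)), donor, donor, np.ones_like(donor), roi)
        assert np.all(traces["cell"].mfi_donor[:50] == 0.0)
        assert np.all(traces["cell"].mfi_donor[50:] == 100.0)

    def test_pixel_count_partition(self, roi):
        donor = self._stack(2, 1, 1.0)
        traces = compartment_traces(np.arange(2.0), donor, donor, donor, roi)
        assert traces["nucleus"].n_pixels + traces["cytosol"].n_pixels == traces["cell"].n_pixels

    def test_mean_rg_ignores_background(self, roi):
        donor = self._stack(1, 1, 1.0)
        ratio = np.full((1, 1, 12, 12), SENTINEL)
        ratio[0, 0, 5, 5] = 2.0  # single foreground pixel inside the cell
        traces = compartment_traces([0.0], donor, donor, ratio, roi)
        assert traces["cell"].mean_rg[0] == pytest.approx(2.0)
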