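"""Ratiometric FRET quantification: background subtraction, binning,
ratio maps, edge band, regional summaries."""

import numpy as np
import pytest
from skimage import morphology

from endomapper import (
    CalibratedImage,
    FretInput,
    LabeledCompartments,
    bin_image,
    bin_mask,
    edge_band_mask,
    fret_ratio_map,
    generate_fret_fixture,
    region_mean_ratio,
    subtract_background,
)


class TestSubtractBackground:
    def test_flat_channel_goes_to_zero(self):
        ch = CalibratedImage(np.full((10, 10), 100.0), 0.3)
        bg = np.zeros((10, 10), dtype=bool)
        bg[:2, :] = True
        out = subtract_background(ch, bg)
        np.testing.assert_allclose(out.pixels, 0)

    def test_background_mean_subtracted(self):
        px = np.full((4, 4), 50.0)
        px[0, :3] = [10, 12, 14]  # background mean 12
        bg = np.zeros((4, 4), dtype=bool)
        bg[0, :3] = True
        out = subtract_background(CalibratedImage(px, 0.3), bg)
        assert out.pixels[2, 2] == pytest.approx(38.0)

    def test_zero_background_is_identity(self):
        px = np.arange(16.0).reshape(4, 4) + 1
        bg = np.zeros((4, 4), dtype=bool)
        bg[0, 0] = True
        px[0, 0] = 0.0
        out = subtract_background(CalibratedImage(px, 0.3), bg)
        np.testing.assert_allclose(out.pixels, px)

    def test_negative_results_kept_not_clamped(self):
        px = np.full((4, 4), 5.0)
        bg = np.zeros((4, 4), dtype=bool)
        bg[0, :] = True
        px[0, :] = 20.0
        out = subtract_background(CalibratedImage(px, 0.3), bg)
        assert out.pixels.min() == pytest.approx(-15.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subtract_background(
                CalibratedImage(np.ones((4, 4)), 0.3), np.zeros((4, 4), dtype=bool)
            )


class TestBinImage:
    def test_factor_one_identity(self):
        ch = CalibratedImage(np.arange(16.0).reshape(4, 4), 0.3)
        out = bin_image(ch, 1)
        np.testing.assert_array_equal(out.pixels, ch.pixels)
        assert out.pixel_size_um == 0.3

    def test_block_mean(self):
        ch = CalibratedImage(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.3)
        out = bin_image(ch, 2)
        assert out.pixels.shape == (1, 1)
        assert out.pixels[0, 0] == pytest.approx(2.5)
        assert out.pixel_size_um == pytest.approx(0.6)

    @pytest.mark.parametrize("factor", [2, 3])
    def test_operating_points_drop_trailing(self, factor):
        ch = CalibratedImage(np.ones((7, 7)), 0.3)
        out = bin_image(ch, factor)
        assert out.pixels.shape == (7 // factor, 7 // factor)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            bin_image(CalibratedImage(np.ones((4, 4)), 0.3), 0)


class TestFretRatioMap:
    def test_uniform_double_ratio(self):
        inp = generate_fret_fixture(true_ratio=2.0)
        rmap = fret_ratio_map(inp)
        assert np.allclose(rmap.ratio[rmap.valid_mask], 2.0, atol=1e-9)

    def test_pointwise_ratio(self):
        # yfp 30, cfp 20 after subtraction -> 1.5
        h = w = 20
        cell = np.zeros((h, w), dtype=bool)
        cell[5:15, 5:15] = True
        bg = np.zeros((h, w), dtype=bool)
        bg[:2, :] = True
        cfp = np.zeros((h, w))
        yfp = np.zeros((h, w))
        cfp[cell] = 20.0
        yfp[cell] = 30.0
        inp = FretInput(
            CalibratedImage(cfp, 0.334), CalibratedImage(yfp, 0.334), cell, bg
        )
        rmap = fret_ratio_map(inp)
        assert rmap.ratio[10, 10] == pytest.approx(1.5)

    def test_zero_cfp_pixel_invalid(self):
        h = w = 20
        cell = np.zeros((h, w), dtype=bool)
        cell[5:15, 5:15] = True
        bg = np.zeros((h, w), dtype=bool)
        bg[:2, :] = True
        cfp = np.zeros((h, w))
        yfp = np.zeros((h, w))
        cfp[cell] = 20.0
        yfp[cell] = 30.0
        cfp[10, 10] = 0.0
        inp = FretInput(
            CalibratedImage(cfp, 0.334), CalibratedImage(yfp, 0.334), cell, bg
        )
        rmap = fret_ratio_map(inp)
        assert not rmap.valid_mask[10, 10]
        assert np.isnan(rmap.ratio[10, 10])

    def test_joint_rescaling_invariance(self):
        base = generate_fret_fixture(true_ratio=1.7, noise_sd=0.0)
        scaled = FretInput(
            base.cfp.with_pixels(base.cfp.pixels * 3.0),
            base.yfp.with_pixels(base.yfp.pixels * 3.0),
            base.cell_mask,
            base.background_region,
        )
        r1 = fret_ratio_map(base)
        r2 = fret_ratio_map(scaled)
        np.testing.assert_allclose(
            r1.ratio[r1.valid_mask], r2.ratio[r2.valid_mask], rtol=1e-9
        )

    @pytest.mark.parametrize("factor", [1, 2, 3])
    def test_binning_invariance_on_uniform_ratio(self, factor):
        inp = generate_fret_fixture(true_ratio=2.0, bin_factor=factor)
        rmap = fret_ratio_map(inp)
        cell = bin_mask(inp.cell_mask, factor)
        assert region_mean_ratio(rmap, cell) == pytest.approx(2.0, abs=1e-9)

    def test_all_invalid_rejected(self):
        h = w = 10
        cell = np.zeros((h, w), dtype=bool)
        cell[5:8, 5:8] = True
        bg = np.zeros((h, w), dtype=bool)
        bg[0, :] = True
        zeros = CalibratedImage(np.zeros((h, w)), 0.3)
        with pytest.raises(ValueError):
            fret_ratio_map(FretInput(zeros, zeros, cell, bg))


class TestEdgeBandMask:
    def test_band_width_and_morphological_oracle(self):
        """1.67 um at 0.334 um/px -> 5 px band; the band must equal
        mask minus disk-erosion, computed here independently."""
        mask = np.zeros((140, 140), dtype=bool)
        mask[20:120, 20:120] = True  # 100x100 square cell
        band = edge_band_mask(mask, 1.67, 0.334)
        width = round(1.67 / 0.334)
        assert width == 5
        oracle = mask & ~morphology.erosion(mask, morphology.disk(width))
        np.testing.assert_array_equal(band, oracle)
        # square-approximation sanity bound: disk erosion shrinks at least
        # as much as nothing and at most as a width-5 frame on each side
        assert band.sum() >= 100**2 - 90**2

    def test_band_subset_and_exact_partition(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 5:55] = True
        band = edge_band_mask(mask, 1.67, 0.334)
        assert not np.any(band & ~mask)
        interior = mask & ~band
        np.testing.assert_array_equal(band | interior, mask)

    def test_thin_cell_band_is_entire_cell(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[9:12, 5:55] = True  # 3 px thick, thinner than 2 x 5 px band
        band = edge_band_mask(mask, 1.67, 0.334)
        np.testing.assert_array_equal(band, mask)

    def test_subpixel_band_rejected(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(ValueError, match="0 px"):
            edge_band_mask(mask, 0.1, 0.334)


class TestRegionMeanRatio:
    def _uniform_map(self, value=2.0):
        inp = generate_fret_fixture(true_ratio=value)
        return fret_ratio_map(inp), inp

    def test_uniform_region_mean(self):
        rmap, inp = self._uniform_map(2.0)
        assert region_mean_ratio(rmap, inp.cell_mask) == pytest.approx(2.0)

    def test_mean_of_known_values(self):
        from endomapper.fret import RatioMap

        ratio = np.full((3, 3), np.nan)
        valid = np.zeros((3, 3), dtype=bool)
        ratio[0, :] = [1.0, 2.0, 3.0]
        valid[0, :] = True
        rmap = RatioMap(ratio, valid, 0.3)
        region = np.zeros((3, 3), dtype=bool)
        region[0, :] = True
        assert region_mean_ratio(rmap, region) == pytest.approx(2.0)

    def test_whole_cell_edge_and_compartments_agree_on_uniform(self):
        rmap, inp = self._uniform_map(2.0)
        band = edge_band_mask(inp.cell_mask, 1.67, 0.334)
        lm = np.zeros(rmap.shape, dtype=int)
        lm[50:60, 50:60] = 1
        per_comp = region_mean_ratio(rmap, LabeledCompartments(lm, 0.334))
        assert region_mean_ratio(rmap, inp.cell_mask) == pytest.approx(2.0, abs=1e-9)
        assert region_mean_ratio(rmap, band) == pytest.approx(2.0, abs=1e-9)
        assert per_comp[0] == pytest.approx(2.0, abs=1e-9)

    def test_region_without_valid_pixels_missing(self):
        rmap, inp = self._uniform_map()
        region = np.zeros(rmap.shape, dtype=bool)
        region[0, 0] = True  # outside the cell
        assert region_mean_ratio(rmap, region) is None


class TestFretInputValidation:
    def test_overlapping_background_rejected(self):
        cell = np.ones((10, 10), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            FretInput(
                CalibratedImage(np.ones((10, 10)), 0.3),
                CalibratedImage(np.ones((10, 10)), 0.3),
                cell,
                cell,
            )
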