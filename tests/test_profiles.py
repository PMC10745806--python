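"""Band excision, density binning, mean profiles, and group stacks."""

import numpy as np
import pytest

from axoquant.collateral_mask import CollateralMask
from axoquant.profiles import (density_grid, longitudinal_profile,
                               remove_shaft_band, stack_and_project,
                               transverse_profile)
from axoquant.straighten import StraightenedImage

PS = 0.2483


def make_mask_image(pixels, ps=PS, valid=None):
    pixels = np.asarray(pixels, dtype=bool)
    if valid is None:
        valid = np.ones_like(pixels, dtype=bool)
    return CollateralMask(pixels, valid, ps, ps, pixels.shape[1] * ps,
                          (pixels.shape[0] - 1) * ps)


def random_cut_mask(rng, rows=60, cols=101, ps=PS, band=5.0):
    mask = make_mask_image(rng.random((rows, cols)) < 0.15, ps=ps)
    return remove_shaft_band(mask, band_um=band)


class TestRemoveShaftBand:
    def test_remaining_width_about_20um(self):
        cut = random_cut_mask(np.random.default_rng(0), cols=101, ps=0.25)
        excluded_cols = (~cut.valid).all(axis=0).sum()
        remaining = (101 - excluded_cols) * 0.25
        assert abs(remaining - 20.0) <= 2 * 0.25

    def test_foreground_only_in_band_gives_zero_profiles(self):
        pix = np.zeros((40, 101), bool)
        pix[:, 48:53] = True  # all within ±0.62 µm of center
        cut = remove_shaft_band(make_mask_image(pix, ps=0.25), 5.0)
        grid = density_grid(cut)
        assert grid.values[~grid.excluded].sum() == 0

    def test_pixels_outside_band_untouched(self, rng):
        mask = make_mask_image(rng.random((30, 101)) < 0.2, ps=0.25)
        cut = remove_shaft_band(mask, 5.0)
        outside = cut.valid
        assert np.array_equal(mask.pixels[outside], cut.pixels[outside])
        assert np.array_equal(mask.pixels, cut.pixels)

    def test_band_wider_than_image_rejected(self):
        mask = make_mask_image(np.zeros((5, 21), bool), ps=0.25)
        with pytest.raises(ValueError):
            remove_shaft_band(mask, band_um=6.0)


class TestDensityGrid:
    def test_empty_mask_all_zero(self, rng):
        cut = remove_shaft_band(make_mask_image(np.zeros((30, 101), bool)), 5.0)
        grid = density_grid(cut)
        assert not grid.values.any()

    def test_single_pixel_density_value(self):
        # one foreground pixel at 0.2483 µm pixels:
        # density = 1 / (4 · 0.2483 · 0.2483) ≈ 4.055 µm⁻²
        pix = np.zeros((20, 101), bool)
        cut = remove_shaft_band(make_mask_image(pix), 5.0)
        lo, _ = cut.band_cols
        pix[7, lo - 3] = True  # inside the bin adjacent to the band
        cut = remove_shaft_band(make_mask_image(pix), 5.0)
        grid = density_grid(cut)
        expected = 1.0 / (4 * PS * PS)
        assert expected == pytest.approx(4.055, abs=0.001)
        assert grid.values.max() == pytest.approx(expected)
        # conservation: summing density × area recovers the single pixel
        assert (grid.values * grid.cell_area_um2).sum() == pytest.approx(1.0)

    def test_bin_width_is_0_9932_um_at_reference_pixel_size(self):
        cut = random_cut_mask(np.random.default_rng(1))
        grid = density_grid(cut)
        assert grid.bin_width_x_um == pytest.approx(0.9932)

    def test_conservation_on_random_masks(self, rng):
        for _ in range(20):
            cut = random_cut_mask(rng)
            grid = density_grid(cut)
            covered_fg = (cut.pixels & grid.coverage).sum()
            assert (grid.values * grid.cell_area_um2).sum() == pytest.approx(
                covered_fg, abs=1e-9)

    def test_requires_band_excision(self):
        with pytest.raises(ValueError, match="remove_shaft_band"):
            density_grid(make_mask_image(np.zeros((5, 101), bool)))

    def test_bad_bin_px(self):
        cut = random_cut_mask(np.random.default_rng(2))
        with pytest.raises(ValueError):
            density_grid(cut, bin_px=0)

    def test_cells_with_invalid_pixels_excluded(self, rng):
        pix = rng.random((30, 101)) < 0.2
        valid = np.ones_like(pix, dtype=bool)
        valid[:5, :10] = False  # e.g. out-of-bounds corner
        cut = remove_shaft_band(make_mask_image(pix, valid=valid), 5.0)
        grid = density_grid(cut)
        assert grid.excluded[:5, :2].all()


class TestProfiles:
    def test_uniform_grid_gives_flat_transverse_profile(self, rng):
        cut = remove_shaft_band(make_mask_image(np.ones((40, 101), bool)), 5.0)
        grid = density_grid(cut)
        prof = transverse_profile([grid])
        d = 4 / grid.cell_area_um2  # every cell holds 4 foreground pixels
        assert np.allclose(prof.values, d)

    def test_two_image_linearity(self, rng):
        base = np.zeros((40, 101), bool)
        g1 = density_grid(remove_shaft_band(make_mask_image(np.ones_like(base)), 5.0))
        g0 = density_grid(remove_shaft_band(make_mask_image(base), 5.0))
        prof = transverse_profile([g0, g1])
        single = transverse_profile([g1])
        assert np.allclose(prof.values, single.values / 2)

    def test_transverse_means_match_brute_force(self, rng):
        cut = random_cut_mask(rng)
        grid = density_grid(cut)
        prof = transverse_profile([grid])
        for j in range(grid.values.shape[1]):
            vals = [grid.values[i, j] for i in range(grid.values.shape[0])
                    if not grid.excluded[i, j]]
            assert prof.values[j] == pytest.approx(np.mean(vals))

    def test_longitudinal_means_match_brute_force(self, rng):
        cut = random_cut_mask(rng)
        grid = density_grid(cut)
        prof = longitudinal_profile([grid])
        for i in range(grid.values.shape[0]):
            vals = [grid.values[i, j] for j in range(grid.values.shape[1])
                    if not grid.excluded[i, j]]
            assert prof.values[i] == pytest.approx(np.mean(vals))

    def test_weighted_profile_means_agree_with_grand_mean(self, rng):
        grids = [density_grid(random_cut_mask(rng, rows=r))
                 for r in (50, 60, 70)]
        tp = transverse_profile(grids)
        lp = longitudinal_profile(grids)
        grand = (sum(g.values[~g.excluded].sum() for g in grids)
                 / sum((~g.excluded).sum() for g in grids))
        t_mean = np.nansum(tp.values * tp.cell_counts) / tp.cell_counts.sum()
        l_mean = np.nansum(lp.values * lp.cell_counts) / lp.cell_counts.sum()
        assert t_mean == pytest.approx(grand, rel=1e-9)
        assert l_mean == pytest.approx(grand, rel=1e-9)

    def test_no_transverse_positions_inside_band(self, rng):
        grid = density_grid(random_cut_mask(rng))
        prof = transverse_profile([grid])
        assert np.all(np.abs(prof.positions) > 2.5 - 1e-9)

    def test_shorter_images_omitted_from_far_positions(self, rng):
        g_short = density_grid(random_cut_mask(rng, rows=30))
        g_long = density_grid(random_cut_mask(rng, rows=50))
        prof = longitudinal_profile([g_short, g_long])
        assert prof.per_image.shape == (2, 50)
        assert np.isnan(prof.per_image[0, 40])
        assert not np.isnan(prof.per_image[1, 40])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            transverse_profile([])
        with pytest.raises(ValueError):
            longitudinal_profile([])


class TestStackAndProject:
    def test_single_image_avg_equals_max_equals_image(self, rng):
        cut = random_cut_mask(rng)
        s = stack_and_project([cut])
        assert np.allclose(s.avg_projection[cut.valid],
                           cut.pixels[cut.valid])
        assert np.allclose(s.max_projection[cut.valid],
                           cut.pixels[cut.valid])

    def test_two_identical_images(self, rng):
        pix = rng.random((30, 41))
        im = StraightenedImage(pix, np.ones_like(pix, bool), PS, PS,
                               41 * PS, 29 * PS)
        s = stack_and_project([im, im])
        assert np.allclose(s.avg_projection, pix)
        assert np.allclose(s.max_projection, pix)

    def test_unequal_lengths_match_padding_aware_loop(self, rng):
        ims = []
        for rows in (20, 35):
            pix = rng.random((rows, 21))
            ims.append(StraightenedImage(pix, np.ones_like(pix, bool),
                                         PS, PS, 21 * PS, (rows - 1) * PS))
        s = stack_and_project(ims)
        for y in range(35):
            for x in range(21):
                vals = [im.pixels[y, x] for im in ims
                        if y < im.pixels.shape[0]]
                assert s.avg_projection[y, x] == pytest.approx(np.mean(vals))
                assert s.max_projection[y, x] == pytest.approx(max(vals))

    def test_mixed_types_rejected(self, rng):
        cut = random_cut_mask(rng)
        pix = np.ones((10, 101))
        im = StraightenedImage(pix, np.ones_like(pix, bool), PS, PS,
                               101 * PS, 9 * PS)
        with pytest.raises(ValueError):
            stack_and_project([cut, im])
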