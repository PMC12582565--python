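import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_isodata as skimage_isodata

from perimt.images import CellMask, ImageStack
from perimt.params import PixelCalibration
from perimt.preprocess import (
    isodata_threshold,
    isodata_value,
    max_intensity_projection,
    per_cell_perfect_threshold,
    peripheral_band,
    population_isodata_threshold,
    richardson_lucy_deconvolve,
)
from perimt.synthetic import FilamentSpec, render_mt_image

CAL = PixelCalibration(pixel_size_um=0.1)


class TestRichardsonLucy:
    def test_blurred_point_sharpens(self):
        img = np.zeros((51, 51))
        img[25, 25] = 1000.0
        blurred = ndimage.gaussian_filter(img, 2.0)
        stack = ImageStack(blurred, CAL)
        out = richardson_lucy_deconvolve(stack, psf_sigma_um=0.2, iterations=30)
        assert out.pixels.max() > blurred.max()

    def test_flux_approximately_conserved(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.poisson(50, (64, 64)).astype(float), 1.5)
        stack = ImageStack(img, CAL)
        out = richardson_lucy_deconvolve(stack, psf_sigma_um=0.15, iterations=20)
        assert np.all(out.pixels >= 0)
        assert abs(out.pixels.sum() - img.sum()) / img.sum() < 0.01

    def test_zero_iterations_rejected(self):
        stack = ImageStack(np.ones((8, 8)), CAL)
        with pytest.raises(ValueError, match="iterations"):
            richardson_lucy_deconvolve(stack, psf_sigma_um=0.15, iterations=0)

    def test_resolves_two_parallel_lines(self):
        """Two lines 0.4 µm apart blurred with sigma = 0.15 µm: after
        deconvolution the cross profile shows two maxima and a much deeper
        dip between them than in the blurred input."""
        img = np.zeros((60, 60))
        img[28, 10:50] = 1000.0
        img[32, 10:50] = 1000.0  # 4 px = 0.4 µm apart
        blurred = ndimage.gaussian_filter(img, 1.5) + 1.0  # sigma 0.15 µm
        out = richardson_lucy_deconvolve(ImageStack(blurred, CAL), 0.15, 30)

        def n_maxima(profile):
            interior = profile[1:-1]
            return int(np.sum((interior > profile[:-2]) & (interior >= profile[2:])
                              & (interior > 0.3 * profile.max())))

        def dip_ratio(profile):
            return profile[30] / profile.max()  # midpoint between the lines

        assert n_maxima(out.pixels[:, 30]) == 2
        assert dip_ratio(out.pixels[:, 30]) < dip_ratio(blurred[:, 30]) - 0.2


class TestProjection:
    def test_single_slice_identity(self):
        cal = PixelCalibration(0.1, z_step_um=0.4)
        stack = ImageStack(np.arange(16.0).reshape(1, 4, 4), cal, axes="ZYX")
        out = max_intensity_projection(stack)
        assert np.array_equal(out.pixels, stack.pixels[0])

    def test_pixelwise_maximum(self):
        cal = PixelCalibration(0.1, z_step_um=0.4)
        pix = np.zeros((3, 1, 1))
        pix[:, 0, 0] = [1, 0, 5]
        out = max_intensity_projection(ImageStack(pix, cal, axes="ZYX"))
        assert out.pixels[0, 0] == 5

    def test_ventral_range_selects_three_slices(self):
        """Seven 0.4 µm slices, ventral 1.2 µm -> slices at 0, 0.4, 0.8 µm."""
        cal = PixelCalibration(0.1, z_step_um=0.4)
        pix = np.zeros((7, 2, 2))
        for i in range(7):
            pix[i] = i
        out = max_intensity_projection(ImageStack(pix, cal, axes="ZYX"),
                                       z_range_um=(0.0, 1.2))
        assert np.all(out.pixels == 2)  # max over slices 0,1,2

    def test_empty_selection_rejected(self):
        cal = PixelCalibration(0.1, z_step_um=0.4)
        stack = ImageStack(np.zeros((3, 2, 2)), cal, axes="ZYX")
        with pytest.raises(ValueError, match="selects no slices"):
            max_intensity_projection(stack, z_range_um=(5.0, 6.0))


class TestIsodata:
    def test_two_level_image_midpoint(self, disk_cell):
        cols = np.arange(disk_cell.mask.shape[1]) % 2 == 0
        img = np.broadcast_to(np.where(cols, 10.0, 100.0),
                              disk_cell.mask.shape).copy()
        result = isodata_threshold(img, disk_cell)
        assert result.threshold == pytest.approx(55.0, abs=1.0)
        assert np.array_equal(result.mt_mask, disk_cell.mask & (img >= result.threshold))

    def test_constant_image_rejected(self, disk_cell):
        with pytest.raises(ValueError, match="constant"):
            isodata_threshold(np.zeros(disk_cell.mask.shape), disk_cell)

    def test_matches_skimage_intermeans(self):
        """Cross-check against the histogram-based isodata of scikit-image."""
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(20, 4, 4000), rng.normal(120, 15, 2000)])
        ours = isodata_value(vals)
        theirs = skimage_isodata(vals, nbins=4096)
        assert abs(ours - theirs) < 3.0

    def test_recall_against_ground_truth_filaments(self, small_cell):
        img, truth = render_mt_image(small_cell, FilamentSpec(n_filaments=25), seed=5)
        result = isodata_threshold(img, small_cell)
        gt = truth.filament_mask & small_cell.mask
        recall = (result.mt_mask & gt).sum() / gt.sum()
        assert recall >= 0.90

    def test_mt_mask_subset_of_cell_mask(self, small_cell):
        img, _ = render_mt_image(small_cell, FilamentSpec(n_filaments=25), seed=6)
        result = isodata_threshold(img, small_cell)
        assert not np.any(result.mt_mask & ~small_cell.mask)


class TestPerfectThreshold:
    def test_bright_periphery_raises_threshold(self, disk_cell):
        """Bright peripheral MT array over a dim interior: the band-local
        background is brighter, so the band-optimized threshold exceeds the
        whole-cell isodata value."""
        band = peripheral_band(disk_cell, 1.0)
        rng = np.random.default_rng(2)
        img = rng.normal(10, 1, disk_cell.mask.shape)
        img[band] += 30.0  # elevated diffuse signal in the band
        img[band] += np.where(rng.random(band.sum()) < 0.5, 70.0, 0.0)
        perfect = per_cell_perfect_threshold(img, disk_cell, 1.0)
        standard = isodata_threshold(img, disk_cell)
        assert perfect.threshold > standard.threshold

    def test_uniform_band_rejected(self, disk_cell):
        img = np.zeros(disk_cell.mask.shape)
        img[peripheral_band(disk_cell, 1.0)] = 5.0
        with pytest.raises(ValueError, match="constant"):
            per_cell_perfect_threshold(img, disk_cell, 1.0)

    def test_band_wider_than_cell_equals_global(self, disk_cell):
        rng = np.random.default_rng(3)
        img = rng.normal(50, 30, disk_cell.mask.shape).clip(0)
        perfect = per_cell_perfect_threshold(img, disk_cell, 50.0)
        standard = isodata_threshold(img, disk_cell)
        assert perfect.threshold == pytest.approx(standard.threshold, rel=1e-9)

    def test_population_threshold_pools_cells(self, disk_cell, small_cell):
        img_a = np.full(disk_cell.mask.shape, 10.0)
        img_a[disk_cell.mask.nonzero()[0][::2], disk_cell.mask.nonzero()[1][::2]] = 100.0
        img_b = np.full(small_cell.mask.shape, 30.0)
        img_b[small_cell.mask.nonzero()[0][::2], small_cell.mask.nonzero()[1][::2]] = 200.0
        t = population_isodata_threshold([img_a, img_b], [disk_cell, small_cell])
        assert 10.0 < t < 200.0


class TestPeripheralBand:
    def test_disk_annulus_area(self, disk_cell):
        band = peripheral_band(disk_cell, 2.0)
        area = band.sum() * CAL.pixel_area_um2
        expected = np.pi * (10.0**2 - 8.0**2)  # 113.1 µm²
        assert abs(area - expected) / expected < 0.02

    def test_monotone_in_width(self, irregular_cell):
        b1 = peripheral_band(irregular_cell, 1.0)
        b2 = peripheral_band(irregular_cell, 2.0)
        assert not np.any(b1 & ~b2)
        assert b2.sum() > b1.sum()

    def test_matches_brute_force_distance(self, irregular_cell):
        """Oracle: exhaustive nearest-outside-pixel search per pixel, with
        the cell edge midway between inside and outside pixel centres."""
        from scipy.spatial import cKDTree

        mask = irregular_cell.mask
        oy, ox = np.nonzero(~mask)
        tree = cKDTree(np.column_stack([ox, oy]))
        yy, xx = np.nonzero(mask)
        d_px, _ = tree.query(np.column_stack([xx, yy]))
        brute = np.zeros(mask.shape, dtype=bool)
        brute[yy, xx] = (d_px - 0.5) * CAL.pixel_size_um <= 1.5
        assert np.array_equal(peripheral_band(irregular_cell, 1.5), brute)

    def test_nonpositive_width_rejected(self, disk_cell):
        with pytest.raises(ValueError, match="width"):
            peripheral_band(disk_cell, 0.0)
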