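import warnings

import numpy as np
import pytest
from scipy import ndimage

from perimt.directionality import (
    angle_to_border,
    bin_directionality,
    compute_orientation_field,
    directionality_vs_distance,
    mean_fraction_histogram,
    pooled_histogram,
)
from perimt.geometry import (
    acute_angle_difference,
    boundary_tangent_oracle,
    compute_border_geometry,
    peripheral_band_mask,
)
from perimt.images import CellMask, ImageStack
from perimt.params import PixelCalibration
from perimt.synthetic import FilamentSpec, render_mt_image
from perimt.synthetic.filaments import draw_segments

CAL = PixelCalibration(pixel_size_um=0.1)


class TestBorderGeometry:
    def test_disk_tangent_perpendicular_to_radius(self, disk_cell):
        geom = compute_border_geometry(disk_cell)
        yy, xx = np.nonzero(disk_cell.mask)
        cy, cx = yy.mean(), xx.mean()
        radial = np.degrees(np.arctan2(yy - cy, xx - cx)) % 180.0
        r = np.hypot(yy - cy, xx - cx)
        sel = r > 20  # away from the centre, where the radial direction is defined
        diff = acute_angle_difference(geom.tangent_deg[yy[sel], xx[sel]],
                                      (radial[sel] + 90.0) % 180.0)
        assert np.percentile(diff, 95) < 3.0

    def test_half_plane_tangent_and_distance(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[:40, :] = True
        cell = CellMask(mask, CAL)
        geom = compute_border_geometry(cell)
        rows = np.arange(5, 20)  # near the y=0 border, far from other edges
        cols = np.arange(80, 120)
        sub_t = geom.tangent_deg[np.ix_(rows, cols)]
        sub_d = geom.distance_um[np.ix_(rows, cols)]
        assert np.all(acute_angle_difference(sub_t, 0.0) < 0.5)
        assert np.allclose(sub_d, rows[:, None] * CAL.pixel_size_um)

    def test_border_pixels_at_zero_distance(self, irregular_cell):
        from perimt.geometry import border_pixels

        geom = compute_border_geometry(irregular_cell)
        border = border_pixels(irregular_cell.mask)
        assert np.all(geom.distance_um[border] == 0.0)

    def test_tangent_matches_contour_fit_oracle(self, irregular_cell):
        geom = compute_border_geometry(irregular_cell)
        oracle, _ = boundary_tangent_oracle(irregular_cell)
        band = peripheral_band_mask(irregular_cell.mask, 1.0, CAL)
        diff = acute_angle_difference(geom.tangent_deg[band], oracle[band])
        assert np.mean(diff <= 5.0) >= 0.95

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:15] = True
        mask[25:35, 25:35] = True
        with pytest.raises(ValueError, match="single connected component"):
            CellMask(mask, CAL)


class TestOrientationField:
    def _filament_image(self, angle):
        ink, geo, _ = draw_segments((80, 80), np.array([[40.0, 40.0]]),
                                    np.array([angle]), 40.0, 3.5, 200.0)
        return ndimage.gaussian_filter(ink, 1.5) + 5.0, geo

    @pytest.mark.parametrize("angle", [0.0, 30.0, 117.0])
    def test_straight_filament_orientation_recovered(self, angle):
        img, geo = self._filament_image(angle)
        field = compute_orientation_field(img, geo, coherence_min=0.8)
        est = field.orientation_deg[field.valid]
        err = acute_angle_difference(np.median(est), angle)
        assert err < 2.0

    def test_uniform_image_all_inconclusive(self):
        img = np.full((50, 50), 10.0)
        mask = np.ones((50, 50), dtype=bool)
        with pytest.warns(UserWarning, match="zero valid"):
            field = compute_orientation_field(img, mask, coherence_min=0.2)
        assert field.valid.sum() == 0
        assert np.all(field.coherence < 1e-6)

    def test_rotation_equivariance(self):
        img, geo = self._filament_image(30.0)
        f0 = compute_orientation_field(img, geo, coherence_min=0.8)
        f90 = compute_orientation_field(np.rot90(img), np.rot90(geo), coherence_min=0.8)
        m0 = np.median(f0.orientation_deg[f0.valid])
        m90 = np.median(f90.orientation_deg[f90.valid])
        # rot90 (counter-clockwise array rotation) shifts orientation by 90°
        assert acute_angle_difference((m0 + 90.0) % 180.0, m90) < 2.0

    def test_valid_requires_mt_mask(self):
        img, geo = self._filament_image(45.0)
        field = compute_orientation_field(img, geo, coherence_min=0.0)
        assert not np.any(field.valid & ~geo)


class TestAngleToBorder:
    def _const_field_geom(self, orient, tangent):
        shape = (10, 10)
        field_valid = np.ones(shape, dtype=bool)
        from perimt.directionality import OrientationField
        from perimt.geometry import BorderGeometry

        field = OrientationField(np.full(shape, float(orient)),
                                 np.ones(shape), field_valid)
        geom = BorderGeometry(np.zeros(shape), np.full(shape, float(tangent)),
                              np.ones(shape, dtype=bool), CAL)
        return field, geom

    @pytest.mark.parametrize("orient,tangent,expected", [
        (100.0, 10.0, 90.0),   # perpendicular
        (57.0, 57.0, 0.0),     # parallel
        (175.0, 5.0, 10.0),    # wrap-around modulo 180
    ])
    def test_acute_angle_cases(self, orient, tangent, expected):
        field, geom = self._const_field_geom(orient, tangent)
        alpha = angle_to_border(field, geom)
        assert np.allclose(alpha, expected)

    def test_shape_mismatch_rejected(self):
        field, _ = self._const_field_geom(0.0, 0.0)
        from perimt.geometry import BorderGeometry

        geom = BorderGeometry(np.zeros((5, 5)), np.zeros((5, 5)),
                              np.ones((5, 5), dtype=bool), CAL)
        with pytest.raises(ValueError, match="shapes differ"):
            angle_to_border(field, geom)


class TestBinning:
    def _geom(self, shape, dist=0.5):
        from perimt.geometry import BorderGeometry

        return BorderGeometry(np.full(shape, dist), np.zeros(shape),
                              np.ones(shape, dtype=bool), CAL)

    def test_all_parallel_fills_first_bin(self):
        angles = np.zeros((6, 6))
        hist = bin_directionality(angles, self._geom((6, 6)))
        assert hist.parallel_fraction == 1.0
        assert hist.n_pixels == 36

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 90, (20, 20))
        hist = bin_directionality(angles, self._geom((20, 20)))
        assert abs(hist.fractions.sum() - 1.0) < 1e-9

    def test_edge_and_tie_semantics(self):
        # 90 goes to the last (closed) bin; a tie on an interior edge (10)
        # goes to the upper bin
        angles = np.array([[90.0, 10.0]])
        hist = bin_directionality(angles, self._geom((1, 2)))
        assert hist.counts[8] == 1
        assert hist.counts[1] == 1
        assert hist.counts[0] == 0

    def test_empty_band_flagged_not_raised(self):
        angles = np.full((4, 4), np.nan)
        hist = bin_directionality(angles, self._geom((4, 4)))
        assert hist.n_pixels == 0
        assert np.all(np.isnan(hist.fractions))

    def test_single_band_consistent_with_bin_directionality(self, small_cell):
        img, _ = render_mt_image(small_cell, FilamentSpec(n_filaments=25), seed=2)
        geom = compute_border_geometry(small_cell)
        thr_mask = img.pixels > np.percentile(img.pixels[small_cell.mask], 80)
        field = compute_orientation_field(img, thr_mask & small_cell.mask)
        angles = angle_to_border(field, geom)
        single = bin_directionality(angles, geom, (0.0, 1.0))
        multi = directionality_vs_distance(angles, geom, [0.0, 1.0])
        assert np.array_equal(single.counts, multi[0].counts)

    def test_bands_partition_valid_pixels(self, small_cell):
        img, _ = render_mt_image(small_cell, FilamentSpec(n_filaments=25), seed=2)
        geom = compute_border_geometry(small_cell)
        thr_mask = img.pixels > np.percentile(img.pixels[small_cell.mask], 80)
        field = compute_orientation_field(img, thr_mask & small_cell.mask)
        angles = angle_to_border(field, geom)
        hists = directionality_vs_distance(angles, geom, [0, 1, 2, 3, 4, 5])
        total = sum(h.n_pixels for h in hists)
        in_range = np.isfinite(angles) & (geom.distance_um < 5.0)
        assert total == int(in_range.sum())

    def test_non_monotone_edges_rejected(self, small_cell):
        geom = compute_border_geometry(small_cell)
        with pytest.raises(ValueError, match="increasing"):
            directionality_vs_distance(np.zeros(small_cell.mask.shape), geom, [0, 2, 1])

    def test_two_zone_cell_parallel_outside_isotropic_inside(self, disk_cell):
        """Parallel filaments confined to the outer 1 µm over an isotropic
        interior: the parallel share must drop with border distance."""
        par = FilamentSpec(n_filaments=60, orientation_model="parallel_to_border",
                          background=0.0, poisson=False, read_noise_sigma=0.0)
        iso = FilamentSpec(n_filaments=120, orientation_model="isotropic",
                          background=0.0, poisson=False, read_noise_sigma=0.0)
        img_p, _ = render_mt_image(disk_cell, par, seed=3, seed_band_um=(0.0, 1.0))
        img_i, _ = render_mt_image(disk_cell, iso, seed=4, seed_band_um=(2.0, 8.0))
        pixels = img_p.pixels + img_i.pixels + 5.0
        geom = compute_border_geometry(disk_cell)
        mt = pixels > 40.0
        field = compute_orientation_field(pixels, mt & disk_cell.mask)
        angles = angle_to_border(field, geom)
        hists = directionality_vs_distance(angles, geom, [0, 1, 2, 3])
        assert hists[0].parallel_fraction > hists[2].parallel_fraction

    def test_pooled_and_mean_summaries(self):
        h1 = bin_directionality(np.zeros((3, 3)), self._geom((3, 3)), cell_id="a")
        h2 = bin_directionality(np.full((3, 3), 45.0), self._geom((3, 3)), cell_id="b")
        pooled = pooled_histogram([h1, h2])
        assert pooled.n_pixels == 18
        assert pooled.fractions[0] == pytest.approx(0.5)
        mean_fr = mean_fraction_histogram([h1, h2])
        assert mean_fr[0] == pytest.approx(0.5)
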