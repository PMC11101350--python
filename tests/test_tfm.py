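"""Virtual TFM: markers, spline field fitting, area strain, aggregation."""

import numpy as np
import pytest

from cellnet.tfm import (
    AreaStrainMap,
    MarkerSet,
    Region,
    aggregate_delta_area_strain,
    attach_region_masks,
    compute_area_strain,
    fit_displacement_field,
    render_marker_image,
    seed_and_displace_markers,
)

REG = Region.centred(100.0)
SQ11 = np.sqrt(1.1)


def _affine(X):
    return (SQ11 - 1.0) * np.asarray(X)


class TestMarkers:
    def test_zero_field_keeps_markers_in_place(self):
        ms = seed_and_displace_markers(lambda X: np.zeros_like(X), REG, 500, 1)
        assert np.array_equal(ms.reference, ms.displaced)

    def test_affine_field_scales_positions(self):
        ms = seed_and_displace_markers(_affine, REG, 500, 1)
        assert np.allclose(ms.displaced, SQ11 * ms.reference)

    def test_seed_reproducibility(self):
        a = seed_and_displace_markers(_affine, REG, 300, 7)
        b = seed_and_displace_markers(_affine, REG, 300, 7)
        assert np.array_equal(a.reference, b.reference)

    def test_low_marker_count_warns(self):
        with pytest.warns(UserWarning, match="under-determined"):
            seed_and_displace_markers(_affine, REG, 50, 1)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            MarkerSet(np.zeros((5, 2)), np.zeros((4, 2)), REG)


class TestImage:
    def test_image_dimensions_follow_resolution(self):
        img = render_marker_image(np.array([[0.0, 0.0]]), REG)
        assert img.shape == (int(np.ceil(100.0 / 0.229)),) * 2
        assert img.dtype == np.uint8

    def test_single_marker_peaks_at_its_position(self):
        img = render_marker_image(np.array([[0.0, 0.0]]), REG)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(ix - 50.0 / 0.229) <= 1
        assert abs(iy - 50.0 / 0.229) <= 1

    def test_two_markers_two_maxima(self):
        img = render_marker_image(np.array([[-20.0, 0.0], [20.0, 0.0]]), REG).astype(float)
        from scipy.ndimage import maximum_filter

        peaks = (img == maximum_filter(img, size=9)) & (img > 100)
        assert peaks.sum() >= 2

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            render_marker_image(np.zeros((1, 2)), Region(0, 0, 0.01, 0.01), pixel_size=1.0)


class TestSplineFit:
    def test_affine_deformation_reproduced_exactly(self):
        """An affine map lies in the cubic spline space: the fit recovers
        it to numerical precision (< 1e-6 μm)."""
        ms = seed_and_displace_markers(_affine, REG, 1500, 3)
        fld = fit_displacement_field(ms)
        test = np.random.default_rng(0).uniform(-45, 45, (300, 2))
        err = np.abs(fld.evaluate(test) - _affine(test)).max()
        assert err < 1e-6

    def test_zero_displacements_give_zero_field(self):
        ms = seed_and_displace_markers(lambda X: np.zeros_like(X), REG, 800, 2)
        fld = fit_displacement_field(ms)
        assert np.abs(fld.coef).max() < 1e-10

    def test_known_spline_field_recovered(self):
        """Markers sampled from a random 8x8 spline field return its
        coefficients (relative error < 1e-3 with 2000 markers)."""
        rng = np.random.default_rng(4)
        ref = rng.uniform(-45, 45, size=(2000, 2))
        truth = fit_displacement_field(
            MarkerSet(ref, ref + rng.normal(0, 0.5, ref.shape), REG)
        )
        truth.coef = rng.normal(0.0, 1.0, size=truth.coef.shape)
        ms = MarkerSet(ref, ref + truth.evaluate(ref), REG)
        fld = fit_displacement_field(ms)
        rel = np.abs(fld.coef - truth.coef).max() / np.abs(truth.coef).max()
        assert rel < 1e-3

    def test_insufficient_markers_rejected(self):
        ref = np.random.default_rng(1).uniform(-45, 45, (40, 2))
        with pytest.raises(ValueError):
            fit_displacement_field(MarkerSet(ref, ref, REG))


class TestAreaStrain:
    def _field_from(self, mapping, n=1200, seed=5):
        ms = seed_and_displace_markers(mapping, REG, n, seed)
        return fit_displacement_field(ms)

    def test_identity_gives_zero_strain(self):
        smap = compute_area_strain(self._field_from(lambda X: np.zeros_like(X)), 1.0)
        assert np.abs(smap.eps_A).max() < 1e-9
        assert smap.valid.all()

    def test_equibiaxial_stretch_gives_ten_percent(self):
        smap = compute_area_strain(self._field_from(_affine), 1.0)
        assert np.allclose(smap.eps_A, 0.10, atol=1e-9)

    def test_pure_shear_is_area_preserving(self):
        lam = 1.04

        def shear(X):
            X = np.asarray(X)
            return np.column_stack([(lam - 1) * X[:, 0], (1 / lam - 1) * X[:, 1]])

        smap = compute_area_strain(self._field_from(shear), 1.0)
        assert np.abs(smap.eps_A).max() < 1e-9


class TestAggregation:
    def _square_map(self, under_value, around_value, noise=0.0, seed=0):
        n = 120
        x = np.linspace(-30, 30, n)
        rng = np.random.default_rng(seed)
        eps = np.full((n, n), around_value) + noise * rng.normal(size=(n, n))
        smap = AreaStrainMap(
            eps_A=eps, valid=np.ones((n, n), bool), x=x, y=x, pixel_size=x[1] - x[0]
        )
        square = np.array([[-10, -10], [10, -10], [10, 10], [-10, 10]], float)
        attach_region_masks(smap, square)
        smap.eps_A[smap.cell_mask] = under_value + (
            noise * rng.normal(size=int(smap.cell_mask.sum()))
        )
        return smap

    def test_two_level_map_recovers_contrast(self):
        """eps_A = -0.02 under the cell and 0 outside gives Delta = 2%
        under per-region binning; shared-edge binning quantises the
        two levels to bin centres, giving 3/4 of the contrast."""
        smap = self._square_map(-0.02, 0.0, noise=1e-4)
        res = aggregate_delta_area_strain(smap, shared_edges=False)
        assert res.delta == pytest.approx(0.02, abs=1e-3)
        assert res.delta_percent == pytest.approx(2.0, abs=0.1)
        shared = aggregate_delta_area_strain(smap)
        assert shared.delta == pytest.approx(0.015, abs=1e-3)

    def test_uniform_map_gives_zero_delta(self):
        smap = self._square_map(0.05, 0.05)
        res = aggregate_delta_area_strain(smap)
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_vicinity_mask_is_disjoint_and_four_times_larger(self):
        smap = self._square_map(0.0, 0.0)
        assert not (smap.cell_mask & smap.vicinity_mask).any()
        ratio = (smap.vicinity_mask.sum() + smap.cell_mask.sum()) / smap.cell_mask.sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_histogram_occurrences_cover_regions(self):
        smap = self._square_map(-0.01, 0.01, noise=2e-3)
        res = aggregate_delta_area_strain(smap)
        assert res.under_hist[0].sum() == smap.cell_mask.sum()
        assert res.vicinity_hist[0].sum() == smap.vicinity_mask.sum()

    def test_missing_masks_rejected(self):
        smap = AreaStrainMap(
            eps_A=np.zeros((4, 4)), valid=np.ones((4, 4), bool),
            x=np.arange(4.0), y=np.arange(4.0), pixel_size=1.0,
        )
        with pytest.raises(ValueError):
            aggregate_delta_area_strain(smap)
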