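import numpy as np
import pytest

from petlung.localizer import (
    ApexNotFoundError,
    BodyNotFoundError,
    LocalizerParams,
    air_fraction,
    binarize_air,
    central_band,
    detect_lung_apex,
    extract_lung_volume,
    find_contours,
    select_body_contour,
)
from petlung.phantom import NoduleSpec, PhantomSpec, generate_phantom
from petlung.volumes import CtVolume, PetVolume, StudyPair


def _ellipse(shape, center, semi):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1


class TestBinarizeAir:
    def test_uniform_air_slice(self):
        assert binarize_air(np.full((8, 8), -1000.0)).all()

    def test_uniform_tissue_slice(self):
        assert not binarize_air(np.full((8, 8), 40.0)).any()

    def test_phantom_slice_matches_truth_masks(self, fast_phantom, fast_spec):
        study, truth = fast_phantom
        k = truth.apex_slice + 5
        got = binarize_air(study.ct.voxels[k])
        body = _ellipse(
            study.ct.voxels[k].shape, fast_spec.body_center, fast_spec.body_semiaxes
        )
        expected_inside = truth.lung_mask[k]
        np.testing.assert_array_equal(got & body, expected_inside)


class TestFindContours:
    def test_filled_ellipse_area_near_analytic(self):
        mask = _ellipse((100, 100), (50, 50), (20, 30))
        regions = find_contours(mask)
        assert len(regions) == 1
        assert regions[0].area_px == pytest.approx(np.pi * 20 * 30, rel=0.02)
        assert regions[0].centroid == pytest.approx((50, 50), abs=0.5)

    def test_two_disjoint_squares_exact_pixel_areas(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:10, 2:10] = True  # 64 px
        mask[20:30, 20:35] = True  # 150 px
        regions = sorted(find_contours(mask), key=lambda r: r.area_px)
        assert [r.area_px for r in regions] == [64.0, 150.0]

    def test_empty_mask_gives_empty_list(self):
        assert find_contours(np.zeros((10, 10), dtype=bool)) == []

    def test_enclosed_holes_not_reported_and_counted_in_area(self):
        body = _ellipse((100, 100), (50, 50), (30, 40))
        holes = _ellipse((100, 100), (50, 35), (10, 8)) | _ellipse(
            (100, 100), (50, 65), (10, 8)
        )
        regions = find_contours(body & ~holes)
        assert len(regions) == 1
        assert regions[0].area_px == pytest.approx(body.sum(), rel=0.01)


class TestSelectBody:
    params = LocalizerParams()

    def test_centered_ellipse_beats_corner_blob(self):
        mask = _ellipse((100, 100), (50, 50), (28, 38))  # ~33% of image
        mask[:5, :5] = True  # 1% corner blob
        regions = find_contours(mask)
        body = select_body_contour(regions, (100, 100), self.params)
        assert body.centroid == pytest.approx((50, 50), abs=1.0)

    def test_all_regions_near_edge_raises(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[0:40, 0:40] = True  # large but cornered: centroid (19.5, 19.5) > margin 10
        mask2 = np.zeros((100, 100), dtype=bool)
        mask2[:8, :] = True  # strip along the top edge
        regions = find_contours(mask2)
        with pytest.raises(BodyNotFoundError):
            select_body_contour(regions, (100, 100), self.params)

    def test_body_beats_scanner_table_strip(self):
        body = _ellipse((128, 128), (64, 64), (40, 52))
        table = np.zeros((128, 128), dtype=bool)
        table[120:, :] = True  # artifact strip along the bottom edge
        regions = find_contours(body | table)
        got = select_body_contour(regions, (128, 128), self.params)
        assert got.centroid == pytest.approx((64, 64), abs=1.0)

    def test_tiny_regions_filtered_by_area(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[45:55, 45:55] = True  # 1% of image, centered
        with pytest.raises(BodyNotFoundError):
            select_body_contour(find_contours(mask), (100, 100), self.params)


class TestCentralBand:
    def test_uniform_body_band_width_matches_fraction(self):
        mask = np.ones((50, 100), dtype=bool)
        [region] = find_contours(mask)
        lo, hi = central_band(region, (50, 100), 0.33)
        width = hi - lo + 1
        assert abs(width - 33) <= 2

    def test_band_fraction_one_spans_body(self):
        mask = np.zeros((50, 100), dtype=bool)
        mask[:, 20:80] = True
        [region] = find_contours(mask)
        lo, hi = central_band(region, (50, 100), 0.999)
        assert lo <= 20 and hi >= 79

    def test_enclosed_area_within_one_column_of_target(self, fast_phantom, fast_spec):
        study, _ = fast_phantom
        sl = study.ct.voxels[2]
        regions = find_contours(~binarize_air(sl))
        body = select_body_contour(regions, sl.shape, LocalizerParams())
        lo, hi = central_band(body, sl.shape, 0.33)
        cols = body.mask.sum(axis=0)
        inside = cols[lo : hi + 1].sum()
        assert inside >= 0.33 * body.area_px
        # narrowest: one column pair less falls below the target
        if lo + 1 <= hi - 1:
            assert cols[lo + 1 : hi].sum() < 0.33 * body.area_px


class TestAirFraction:
    def test_no_air_is_zero(self):
        sl = np.full((64, 64), 40.0)
        sl[10:54, 10:54] = 40.0
        [body] = find_contours(~binarize_air(sl))
        assert air_fraction(sl, body, (0, 63)) == 0.0

    def test_air_outside_band_not_counted(self):
        sl = np.full((64, 64), 40.0)
        sl[20:30, 50:60] = -1000.0  # air pocket on the right
        tissue = ~binarize_air(sl)
        [body] = find_contours(tissue)
        assert air_fraction(sl, body, (0, 40)) == 0.0
        assert air_fraction(sl, body, (45, 63)) > 0.0

    def test_phantom_fraction_matches_truth_count(self, fast_phantom):
        study, truth = fast_phantom
        k = truth.apex_slice + 3
        sl = study.ct.voxels[k]
        body = select_body_contour(find_contours(~binarize_air(sl)), sl.shape, LocalizerParams())
        band = central_band(body, sl.shape, 0.33)
        got = air_fraction(sl, body, band)
        assert got == pytest.approx(truth.air_fraction_per_slice[k], abs=1e-6)


class TestDetectApex:
    def test_phantom_apex_recovered(self, fast_phantom, fast_localizer_params):
        study, truth = fast_phantom
        assert detect_lung_apex(study.ct, fast_localizer_params) == truth.apex_slice

    def test_all_tissue_volume_raises(self):
        ct = CtVolume(np.full((6, 64, 64), 40.0))
        with pytest.raises(ApexNotFoundError):
            detect_lung_apex(ct)

    def test_just_below_threshold_raises(self):
        # body of 10000 px with a central air pocket; a band fraction of 0.98
        # makes the band span the body, so the pocket is fully counted
        params = LocalizerParams(band_fraction=0.98)
        sl = np.full((128, 128), -1000.0, dtype=np.float32)
        sl[10:110, 10:110] = 40.0
        sl[50:60, 40:89] = -1000.0  # 10x49 = 490 px: 4.9% < 5%
        ct = CtVolume(np.stack([sl] * 3))
        with pytest.raises(ApexNotFoundError):
            detect_lung_apex(ct, params)
        sl[50:60, 40:90] = -1000.0  # 500 px: exactly 5.0%
        ct = CtVolume(np.stack([sl] * 3))
        assert detect_lung_apex(ct, params) == 0


class TestExtractLungVolume:
    def test_crop_shapes_and_padding(self, fast_phantom, fast_localizer_params):
        study, truth = fast_phantom
        res = extract_lung_volume(study, fast_localizer_params)
        assert res.ct_crop.shape == (32, 64, 64)
        assert res.pet_crop.shape == (32, 16, 16)
        assert res.apex_slice_index == truth.apex_slice
        assert res.padded_slices == max(0, 32 - (study.ct.shape[0] - truth.apex_slice))

    def test_short_volume_padded_with_air(self, fast_spec, fast_localizer_params):
        spec = PhantomSpec.create("fast", n_slices=24, seed=4, noise_sigma_hu=0.0)
        study, truth = generate_phantom(spec)
        res = extract_lung_volume(study, fast_localizer_params)
        expected_pad = 32 - (24 - truth.apex_slice)
        assert res.padded_slices == expected_pad
        assert (res.ct_crop[-expected_pad:] == -1000.0).all()
        assert (res.pet_crop[-expected_pad:] == 0.0).all()

    def test_nodule_lands_at_predicted_crop_indices(self, nodule_phantom, fast_localizer_params):
        study, truth = nodule_phantom
        res = extract_lung_volume(study, fast_localizer_params)
        # brightest CT voxel inside the lung band should be the nodule center
        ss, rr, cc = np.nonzero(truth.nodule_mask)
        k, r, c = int(ss.mean()), rr.mean(), cc.mean()
        kk = k - res.apex_slice_index
        rrel, crel = r - res.crop_origin[0], c - res.crop_origin[1]
        window = res.ct_crop[kk, int(rrel) - 2 : int(rrel) + 3, int(crel) - 2 : int(crel) + 3]
        assert window.mean() > -200.0  # nodule tissue, not lung air

    def test_determinism(self, fast_phantom, fast_localizer_params):
        study, _ = fast_phantom
        a = extract_lung_volume(study, fast_localizer_params)
        b = extract_lung_volume(study, fast_localizer_params)
        np.testing.assert_array_equal(a.ct_crop, b.ct_crop)
        np.testing.assert_array_equal(a.pet_crop, b.pet_crop)
        assert a.crop_origin == b.crop_origin

    def test_row_translation_equivariance(self, fast_localizer_params):
        # a row shift leaves the (column-anchored) central band unchanged, so
        # apex, contents and origin all translate exactly
        base = PhantomSpec.create("fast", seed=6, noise_sigma_hu=0.0)
        shifted = PhantomSpec.create(
            "fast",
            seed=6,
            noise_sigma_hu=0.0,
            body_center=(base.body_center[0] + 4, base.body_center[1]),
        )
        sa, _ = generate_phantom(base)
        sb, _ = generate_phantom(shifted)
        ra = extract_lung_volume(sa, fast_localizer_params)
        rb = extract_lung_volume(sb, fast_localizer_params)
        assert rb.apex_slice_index == ra.apex_slice_index
        assert rb.crop_origin[0] - ra.crop_origin[0] == 4
        assert rb.crop_origin[1] == ra.crop_origin[1]
        np.testing.assert_array_equal(ra.ct_crop, rb.ct_crop)

    def test_column_shift_moves_crop_origin(self, fast_localizer_params):
        # the band stays anchored at the image center, so a column shift may
        # move the apex by a slice; the crop still follows the body centroid
        base = PhantomSpec.create("fast", seed=6, noise_sigma_hu=0.0)
        shifted = PhantomSpec.create(
            "fast",
            seed=6,
            noise_sigma_hu=0.0,
            body_center=(base.body_center[0], base.body_center[1] - 2),
        )
        sa, _ = generate_phantom(base)
        sb, _ = generate_phantom(shifted)
        ra = extract_lung_volume(sa, fast_localizer_params)
        rb = extract_lung_volume(sb, fast_localizer_params)
        assert rb.crop_origin[1] - ra.crop_origin[1] == -2
        assert abs(rb.apex_slice_index - ra.apex_slice_index) <= 1
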