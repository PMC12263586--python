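"""Image quantification stages against geometry and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zrskit.imaging import (AnnotationError, BoundaryAnnotation,
                            DegenerateInputError, ImageBundle, ImagingError,
                            MaskSet, NoTransfectionError, Orientation,
                            QuantParams, UndefinedActivityError,
                            activity_region, bilateral_denoise, build_masks,
                            build_posterior_mask, build_zpa_mask,
                            measure_region, otsu_threshold, quantify_bundle,
                            relative_activity, segment_limb,
                            transfection_region, to_grayscale)
from zrskit.synthetic import annotation_from_truth, simulate_limb_bundle

from conftest import small_config


def otsu_oracle(values):
    """Exhaustive between-class-variance maximizer; foreground is > t."""
    values = np.asarray(values, dtype=float)
    best_t, best_var = None, -1.0
    for t in sorted(set(values))[:-1]:
        fg, bg = values[values > t], values[values <= t]
        var = len(fg) * len(bg) * (fg.mean() - bg.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def jaccard(a, b):
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


def rect_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestGrayscale:
    def test_single_channel_identity(self):
        img = np.arange(12, dtype=float).reshape(3, 4)
        assert np.array_equal(to_grayscale(img), img)

    def test_gray_rgb_pixel_maps_to_itself(self):
        img = np.full((2, 2, 3), 200.0)
        assert np.allclose(to_grayscale(img), 200.0)

    def test_pure_red_pixel(self):
        img = np.zeros((1, 1, 3))
        img[0, 0, 0] = 100.0
        assert to_grayscale(img)[0, 0] == pytest.approx(21.25)

    def test_unsupported_channels(self):
        with pytest.raises(ImagingError):
            to_grayscale(np.zeros((2, 2, 5)))


class TestBilateral:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 37.0)
        assert np.allclose(bilateral_denoise(img), 37.0)

    def test_step_edge_location_preserved(self):
        img = np.zeros((10, 40))
        img[:, 20:] = 100.0
        out = bilateral_denoise(img, sigma_spatial=3.0, sigma_range=10.0)
        grad_in = np.abs(np.diff(img, axis=1)).sum(axis=0)
        grad_out = np.abs(np.diff(out, axis=1)).sum(axis=0)
        assert grad_out.argmax() == grad_in.argmax()

    def test_salt_and_pepper_variance_reduced(self):
        rng = np.random.default_rng(0)
        img = np.full((30, 30), 50.0)
        idx = rng.integers(0, 30, size=(40, 2))
        img[idx[:20, 0], idx[:20, 1]] = 255.0
        img[idx[20:, 0], idx[20:, 1]] = 0.0
        out = bilateral_denoise(img, sigma_spatial=2.0, sigma_range=200.0)
        assert out.var() < img.var()

    def test_invalid_sigmas(self):
        img = np.ones((4, 4))
        with pytest.raises(ImagingError):
            bilateral_denoise(img, sigma_spatial=0.0)
        with pytest.raises(ImagingError):
            bilateral_denoise(np.arange(16.0).reshape(4, 4), 3.0, -1.0)


class TestOtsu:
    def test_perfectly_bimodal(self):
        values = [0.0] * 10 + [255.0] * 10
        t = otsu_threshold(values)
        assert 0 <= t < 255
        assert np.sum(np.asarray(values) > t) == 10

    def test_three_level_histogram_matches_oracle(self):
        values = [0.0] * 5 + [100.0] * 5 + [200.0] * 5
        assert otsu_threshold(values) == otsu_oracle(values)

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_oracle_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        n_levels = int(rng.integers(2, 256))
        levels = rng.choice(256, size=n_levels, replace=False).astype(float)
        counts = rng.integers(1, 20, size=n_levels)
        values = np.repeat(levels, counts)
        t = otsu_threshold(values)
        assert t == otsu_oracle(values)
        # identical foreground/background partition
        assert np.array_equal(values > t, values > otsu_oracle(values))

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold([7.0] * 10)


class TestSegmentation:
    def test_recovers_known_limb(self, noiseless_bundle):
        bundle, truth = noiseless_bundle
        light = bilateral_denoise(bundle.light, 3.0)
        rows = np.flatnonzero(truth.limb_mask.any(axis=1))
        cols = np.flatnonzero(truth.limb_mask.any(axis=0))
        point = (int(rows.mean()), int(cols.mean()))
        limb = segment_limb(light, truth.boundary_polyline, point)
        assert jaccard(limb, truth.limb_mask) >= 0.95

    def test_boundary_outside_single_blob_is_annotation_error(self):
        img = np.zeros((30, 30))
        img[10:20, 10:20] = 100.0
        with pytest.raises(AnnotationError):
            segment_limb(img, [(0.0, 0.0), (29.0, 0.0)], (15, 15))

    def test_uniform_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment_limb(np.zeros((10, 10)), [(0, 5), (9, 5)])


class TestMasks:
    def test_full_fraction_returns_limb(self):
        limb = rect_mask((30, 40), 5, 25, 10, 35)
        assert np.array_equal(build_posterior_mask(limb, 1.0), limb)

    def test_rectangle_posterior_half(self):
        limb = rect_mask((40, 40), 10, 30, 5, 35)  # rows 10..29
        post = build_posterior_mask(limb, 0.5)
        rows = np.flatnonzero(post.any(axis=1))
        assert rows[0] in (19, 20, 21) and rows[-1] == 29
        assert not np.any(post & ~limb)

    def test_zpa_is_distal_posterior_corner(self):
        limb = rect_mask((40, 50), 10, 30, 5, 45)  # 20 rows x 40 cols
        post = build_posterior_mask(limb, 0.5)
        zpa = build_zpa_mask(limb, post, pd_fraction=0.4, ap_fraction=0.35)
        rows = np.flatnonzero(zpa.any(axis=1))
        cols = np.flatnonzero(zpa.any(axis=0))
        assert rows[-1] == 29 and cols[-1] == 44
        assert len(rows) == 7     # ceil(0.35 * 20)
        assert len(cols) == 16    # ceil(0.4 * 40)

    def test_zpa_equals_limb_at_full_fractions(self):
        limb = rect_mask((20, 20), 2, 18, 2, 18)
        zpa = build_zpa_mask(limb, limb, 1.0, 1.0)
        assert np.array_equal(zpa, limb)

    @pytest.mark.parametrize("seed", range(50))
    def test_nesting_for_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < 0.3
        mask[15, 15] = True  # never empty
        post = build_posterior_mask(mask, float(rng.uniform(0.2, 1.0)))
        if not post.any():
            return
        zpa = build_zpa_mask(mask, post, float(rng.uniform(0.2, 1.0)),
                             float(rng.uniform(0.2, 1.0)))
        assert not np.any(post & ~mask)
        assert not np.any(zpa & ~post)

    def test_empty_limb_rejected(self):
        with pytest.raises(ImagingError):
            build_posterior_mask(np.zeros((5, 5), dtype=bool))

    def test_maskset_validates_nesting(self):
        limb = rect_mask((10, 10), 0, 10, 0, 10)
        outside = rect_mask((10, 10), 0, 10, 0, 10)
        with pytest.raises(ImagingError):
            MaskSet(limb=rect_mask((10, 10), 0, 5, 0, 5),
                    posterior=outside, zpa=outside)


class TestRegions:
    def test_transfection_recovery(self, noiseless_bundle):
        bundle, truth = noiseless_bundle
        ann = annotation_from_truth(truth)
        masks = build_masks(bundle, ann)
        rfp = bilateral_denoise(bundle.rfp, 3.0)
        region, _ = transfection_region(rfp, masks.posterior)
        expected = truth.transfected_mask & masks.posterior
        assert jaccard(region, expected) >= 0.95
        assert not np.any(region & ~masks.posterior)

    def test_no_transfection_detected(self):
        cfg = small_config(transfection_fraction=0.0, noise_sd=0.0, seed=1)
        bundle, truth = simulate_limb_bundle(cfg)
        masks = build_masks(bundle, annotation_from_truth(truth))
        with pytest.raises(NoTransfectionError):
            transfection_region(bundle.rfp, masks.posterior)

    def test_activity_recovery(self, noiseless_bundle):
        bundle, truth = noiseless_bundle
        ann = annotation_from_truth(truth)
        masks = build_masks(bundle, ann)
        rfp = bilateral_denoise(bundle.rfp, 3.0)
        tmask, _ = transfection_region(rfp, masks.posterior)
        gfp = bilateral_denoise(bundle.gfp, 3.0)
        amask, _ = activity_region(gfp, tmask)
        assert jaccard(amask, truth.active_mask & tmask) >= 0.9
        assert not np.any(amask & ~tmask)

    def test_silent_enhancer_gives_empty_region(self):
        cfg = small_config(activity_level=0.0, noise_sd=0.0, seed=1)
        bundle, truth = simulate_limb_bundle(cfg)
        masks = build_masks(bundle, annotation_from_truth(truth))
        tmask, _ = transfection_region(bundle.rfp, masks.posterior)
        amask, _ = activity_region(bundle.gfp, tmask)
        assert amask.sum() < 0.01 * tmask.sum()


class TestMeasurement:
    def test_empty_region(self):
        m = measure_region(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))
        assert (m.pixel_count, m.total_intensity) == (0, 0.0)

    def test_small_region_sum(self):
        img = np.zeros((3, 3))
        img[0, 0], img[1, 1], img[2, 2] = 10, 20, 30
        region = np.eye(3, dtype=bool)
        m = measure_region(img, region)
        assert (m.pixel_count, m.total_intensity) == (3, 60.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_additivity_over_disjoint_regions(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12)) * 100
        a = rng.random((12, 12)) < 0.3
        b = (rng.random((12, 12)) < 0.3) & ~a
        ma, mb, mu = (measure_region(img, r) for r in (a, b, a | b))
        assert mu.pixel_count == ma.pixel_count + mb.pixel_count
        assert mu.total_intensity == pytest.approx(
            ma.total_intensity + mb.total_intensity)

    def test_dimension_mismatch(self):
        with pytest.raises(ImagingError):
            measure_region(np.ones((3, 3)), np.ones((4, 4), dtype=bool))


class TestRelativeActivity:
    def test_basic_ratio(self):
        assert relative_activity(100.0, 200.0) == 0.5
        assert relative_activity(0.0, 50.0) == 0.0

    def test_scale_invariance(self):
        assert relative_activity(30.0, 90.0) == \
            relative_activity(30.0 * 7.3, 90.0 * 7.3)

    def test_zero_rfp_undefined(self):
        with pytest.raises(UndefinedActivityError):
            relative_activity(10.0, 0.0)


class TestQuantifyBundle:
    def test_noiseless_recovery_within_5_percent(self, noiseless_bundle,
                                                 noiseless_record):
        _, truth = noiseless_bundle
        rec = noiseless_record
        assert not rec.excluded
        assert rec.relative_activity == pytest.approx(truth.true_activity,
                                                      rel=0.05)

    def test_metadata_records_thresholds(self, noiseless_record):
        for key in ("rfp_threshold", "gfp_threshold", "sigma_spatial",
                    "posterior_ap_fraction"):
            assert key in noiseless_record.metadata

    def test_rank_recovery_under_noise(self):
        from scipy.stats import spearmanr
        true, est = [], []
        for i, level in enumerate(np.linspace(0.1, 1.0, 20)):
            cfg = small_config(activity_level=float(level), noise_sd=6.0,
                               seed=100 + i)
            bundle, truth = simulate_limb_bundle(cfg)
            rec = quantify_bundle(bundle, annotation_from_truth(truth))
            true.append(truth.true_activity)
            est.append(rec.relative_activity)
        assert spearmanr(true, est).statistic >= 0.9

    def test_no_transfection_gives_excluded_record(self):
        cfg = small_config(transfection_fraction=0.0, noise_sd=0.0, seed=1)
        bundle, truth = simulate_limb_bundle(cfg)
        rec = quantify_bundle(bundle, annotation_from_truth(truth))
        assert rec.excluded
        assert "no transfection detected" in rec.flags

    def test_mask_nesting_on_processed_bundle(self, noiseless_bundle):
        bundle, truth = noiseless_bundle
        masks = build_masks(bundle, annotation_from_truth(truth))
        assert not np.any(masks.zpa & ~masks.posterior)
        assert not np.any(masks.posterior & ~masks.limb)

    def test_rfp_total_monotone_in_mask_with_fixed_threshold(
            self, noiseless_bundle):
        # enlarging the analysis mask from ZPA to Posterior cannot lose RFP
        # signal when the threshold is held fixed
        bundle, truth = noiseless_bundle
        ann = annotation_from_truth(truth)
        params = QuantParams(rfp_threshold=50.0)
        rec_zpa = quantify_bundle(bundle, ann, "zpa", params)
        rec_post = quantify_bundle(bundle, ann, "posterior", params)
        assert rec_post.rfp_total >= rec_zpa.rfp_total

    def test_saturation_flagged_not_excluded(self):
        cfg = small_config(noise_sd=0.0, seed=1, background_level=200.0)
        bundle, truth = simulate_limb_bundle(cfg)  # clips hard at 255
        rec = quantify_bundle(bundle, annotation_from_truth(truth))
        assert any(f.startswith("saturated") for f in rec.flags)
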