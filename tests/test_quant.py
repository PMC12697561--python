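"""ROI quantitation operators against brute-force pixel enumeration oracles."""

import numpy as np
import pytest

from nucdyn.quant import (DiskRoi, LineRoi, RectRoi, RingRoi,
                          annulus_corrected_mean, background_subtract_normalize,
                          bleach_correct, integrated_density, line_scan,
                          remove_outliers_rout, roi_mean)


def brute_disk_mean(img, center, diameter):
    """Oracle: explicit double loop over pixel centers."""
    total = n = 0
    cy, cx = center
    r2 = (diameter / 2.0) ** 2
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            if (i + 0.5 - cy) ** 2 + (j + 0.5 - cx) ** 2 <= r2:
                total += img[i, j]
                n += 1
    return total / n, n


def brute_rect_mean(img, corner, extent):
    total = n = 0
    y0, x0 = corner
    h, w = extent
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            if y0 <= i + 0.5 < y0 + h and x0 <= j + 0.5 < x0 + w:
                total += img[i, j]
                n += 1
    return total / n


@pytest.fixture()
def graded_image():
    rng = np.random.default_rng(7)
    yy, xx = np.mgrid[0:60, 0:60]
    return 50.0 + 0.8 * yy - 0.3 * xx + rng.normal(0, 2.0, (60, 60))


class TestRoiMeans:
    def test_uniform_image_any_roi(self):
        img = np.full((40, 40), 6.25)
        assert roi_mean(img, DiskRoi((20, 20), 11)) == 6.25
        assert roi_mean(img, RectRoi((5, 5), (8, 12))) == 6.25
        ring = RingRoi(np.array([[10, 10], [10, 30], [30, 30], [30, 10]]), 3)
        assert roi_mean(img, ring) == 6.25
        assert roi_mean(img, LineRoi((20, 5), (20, 35), 3)) == 6.25

    def test_disk_on_background(self):
        img = np.full((64, 64), 10.0)
        yy, xx = np.mgrid[0:64, 0:64]
        img[(yy + 0.5 - 32) ** 2 + (xx + 0.5 - 32) ** 2 <= 36] = 100.0
        assert roi_mean(img, DiskRoi((32, 32), 12)) == 100.0

    def test_disk_matches_brute_force_on_graded_image(self, graded_image):
        for center, diam in [((30.0, 30.0), 15.0), ((20.3, 41.7), 9.4)]:
            got = roi_mean(graded_image, DiskRoi(center, diam))
            exp, n = brute_disk_mean(graded_image, center, diam)
            assert got == pytest.approx(exp, abs=1e-9)

    def test_half_covered_rectangle_matches_brute_force(self):
        img = np.full((30, 30), 4.0)
        img[:, 15:] = 20.0
        got = roi_mean(img, RectRoi((10.0, 10.0), (8.0, 10.0)))
        assert got == pytest.approx(brute_rect_mean(img, (10.0, 10.0), (8.0, 10.0)), abs=1e-12)

    def test_integrated_density_is_mean_times_area(self, graded_image):
        roi = DiskRoi((25, 25), 13)
        idens, n = integrated_density(graded_image, roi)
        assert idens == pytest.approx(roi_mean(graded_image, roi) * n, rel=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean(np.zeros((20, 20)), DiskRoi((100, 100), 4))

    def test_ring_matches_brute_force_enumeration(self, graded_image):
        contour = np.array([[15, 20], [20, 40], [40, 42], [42, 18]], float)
        ring = RingRoi(contour, 3.0)
        mask = ring.mask(graded_image.shape)
        # oracle: same geometric rule, naive per-pixel loop
        pts = np.vstack([contour, contour[:1]])
        total = n = 0
        for i in range(60):
            for j in range(60):
                d = min(
                    _seg_dist(i + 0.5, j + 0.5, pts[k], pts[k + 1])
                    for k in range(len(pts) - 1)
                )
                if d <= 1.5:
                    total += graded_image[i, j]
                    n += 1
        assert roi_mean(graded_image, ring) == pytest.approx(total / n, abs=1e-9)
        assert mask.sum() == n


def _seg_dist(py, px, a, b):
    ay, ax = a
    by, bx = b
    vy, vx = by - ay, bx - ax
    L2 = vy * vy + vx * vx
    if L2 == 0:
        return np.hypot(py - ay, px - ax)
    t = min(1.0, max(0.0, ((py - ay) * vy + (px - ax) * vx) / L2))
    return np.hypot(py - (ay + t * vy), px - (ax + t * vx))


class TestNormalization:
    def test_series_equal_baseline_all_ones(self):
        out = background_subtract_normalize(np.full(5, 120.0), 20.0, 120.0, 20.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_mean_equal_background_zero(self):
        out = background_subtract_normalize(np.full(5, 20.0), 20.0, 120.0, 20.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linearity(self):
        m = np.array([30.0, 50.0, 90.0])
        base = background_subtract_normalize(m, 10.0, 110.0, 10.0)
        doubled = background_subtract_normalize(2 * m - 10.0, 10.0, 110.0, 10.0)
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-12)

    def test_rejects_baseline_below_background(self):
        with pytest.raises(ValueError):
            background_subtract_normalize(np.ones(3), 50.0, 40.0, 50.0)


class TestAnnulusCorrection:
    def test_uniform_image_zero(self):
        assert annulus_corrected_mean(np.full((60, 60), 7.0), (30, 30)) == pytest.approx(0.0, abs=1e-12)

    def test_spot_on_uniform_background(self):
        img = np.full((60, 60), 12.0)
        spot = DiskRoi((30.0, 30.0), 15.0).mask(img.shape)
        img[spot] = 90.0
        got = annulus_corrected_mean(img, (30.0, 30.0))
        assert got == pytest.approx(90.0 - 12.0, abs=1e-12)

    def test_constant_offset_invariance(self, graded_image=None):
        rng = np.random.default_rng(3)
        img = rng.random((60, 60)) * 50
        a = annulus_corrected_mean(img, (30, 30))
        b = annulus_corrected_mean(img + 123.4, (30, 30))
        assert a == pytest.approx(b, abs=1e-9)

    def test_graded_background_matches_brute_force(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = 5.0 + 0.5 * yy + 0.2 * xx
        got = annulus_corrected_mean(img, (30.0, 30.0))
        ids, ns = brute_disk_mean(img, (30.0, 30.0), 15.0)
        idl, nl = brute_disk_mean(img, (30.0, 30.0), 25.0)
        local_bg = (idl * nl - ids * ns) / (nl - ns)
        assert got == pytest.approx(ids - local_bg, abs=1e-9)

    def test_pixel_size_rescaling(self):
        # same physical geometry at 2x finer sampling -> diameters double
        img = np.full((120, 120), 4.0)
        spot = DiskRoi((60.0, 60.0), 30.0).mask(img.shape)
        img[spot] = 40.0
        got = annulus_corrected_mean(img, (60.0, 60.0), pixel_size_um=0.084)
        assert got == pytest.approx(36.0, abs=1e-12)


class TestBleachCorrect:
    def test_no_decay_is_identity(self):
        rng = np.random.default_rng(1)
        frames = np.tile(rng.random((20, 20)) * 100, (8, 1, 1))
        corrected, info = bleach_correct(frames)
        np.testing.assert_allclose(corrected, frames, rtol=1e-6)

    def test_pure_exponential_decay_inverted(self):
        t = np.arange(15)
        scene = np.ones((15, 25, 25)) * 80.0 * np.exp(-0.12 * t)[:, None, None]
        corrected, info = bleach_correct(scene)
        means = corrected.reshape(15, -1).mean(axis=1)
        np.testing.assert_allclose(means, 80.0, rtol=1e-6)
        assert info["method"] == "exponential"

    def test_static_spot_mean_constant_after_correction(self):
        rng = np.random.default_rng(2)
        base = np.full((30, 30), 20.0)
        base[10:15, 10:15] = 150.0
        t = np.arange(12)
        frames = base[None] * np.exp(-0.08 * t)[:, None, None]
        corrected, _ = bleach_correct(frames)
        spot_means = corrected[:, 10:15, 10:15].mean(axis=(1, 2))
        np.testing.assert_allclose(spot_means, 150.0, rtol=1e-5)

    def test_requires_five_frames(self):
        with pytest.raises(ValueError):
            bleach_correct(np.ones((4, 5, 5)))


class TestLineScan:
    def test_uniform_image_flat_profile(self):
        d, prof = line_scan(np.full((30, 60), 9.0), (15.0, 5.0), (15.0, 55.0))
        np.testing.assert_allclose(prof, 9.0, atol=1e-12)

    def test_perpendicular_stripe_peak_at_stripe(self):
        img = np.full((30, 60), 2.0)
        img[:, 40] = 80.0
        d, prof = line_scan(img, (15.5, 5.5), (15.5, 55.5))
        assert abs(d[np.argmax(prof)] - (40.5 - 5.5)) <= 1.0

    def test_two_peak_fixture_positions(self):
        img = np.full((40, 90), 5.0)
        img[:, 25] = 60.0
        img[:, 70] = 60.0
        d, prof = line_scan(img, (20.5, 5.5), (20.5, 85.5))
        # local maxima within 1 px of the generative stripe centers
        peak_ds = d[np.flatnonzero((prof > 30))]
        assert np.any(np.abs(peak_ds - 20.0) <= 1.0)
        assert np.any(np.abs(peak_ds - 65.0) <= 1.0)


class TestRoutOutliers:
    def test_clean_gaussian_keeps_nearly_all(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10.0, 2.0, 100)
        kept, flags = remove_outliers_rout(x, q=0.01)
        assert kept.size >= 98

    def test_ten_sd_spike_removed(self):
        rng = np.random.default_rng(12)
        x = np.append(rng.normal(0.0, 1.0, 99), 10.0)
        kept, flags = remove_outliers_rout(x, q=0.01)
        assert flags[-1]

    def test_identical_values_none_removed(self):
        kept, flags = remove_outliers_rout(np.full(20, 3.0))
        assert not flags.any()

    def test_small_samples_untouched(self):
        x = np.array([1.0, 2.0, 100.0])
        kept, flags = remove_outliers_rout(x)
        assert kept.size == 3 and not flags.any()

    def test_false_positive_rate_bounded(self):
        # over 100 seeded replicates, never remove more than 2*Q*n clean points
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 1.0, 100)
            _, flags = remove_outliers_rout(x, q=0.01)
            assert flags.sum() <= 2
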