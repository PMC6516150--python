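"""Histology quantification: hue classes, morphometry, maxent, SHG, nuclei."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse
from skimage.transform import rescale

from vasomech import histology as hq
from vasomech import synthetic

from conftest import kapur_bruteforce


def solid_color(hue_deg, shape=(32, 32)):
    from skimage.color import hsv2rgb

    hsv = np.zeros((*shape, 3))
    hsv[..., 0] = hue_deg / 360.0
    hsv[..., 1] = 0.9
    hsv[..., 2] = 0.9
    return hsv2rgb(hsv)


class TestTrichrome:
    def test_all_green_media_is_pure_collagen(self):
        img = solid_color(120.0)
        mask = np.ones(img.shape[:2], bool)
        collagen, muscle = hq.trichrome_fractions(img, mask)
        assert collagen == pytest.approx(100.0)
        assert muscle == pytest.approx(0.0)

    def test_half_green_half_red(self):
        img = np.vstack([solid_color(120.0, (16, 32)), solid_color(0.0, (16, 32))])
        mask = np.ones(img.shape[:2], bool)
        collagen, muscle = hq.trichrome_fractions(img, mask)
        assert collagen == pytest.approx(50.0)
        assert muscle == pytest.approx(50.0)

    def test_jittered_two_class_recovery(self):
        img = synthetic.make_two_class_image(0.30, 120.0, 0.0, hue_jitter_deg=5.0, seed=3)
        mask = np.ones(img.shape[:2], bool)
        collagen, _ = hq.trichrome_fractions(img, mask)
        assert collagen == pytest.approx(30.0, abs=2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hq.trichrome_fractions(solid_color(120.0), np.zeros((32, 32), bool))

    def test_fractions_invariant_under_integer_rescale(self):
        img = synthetic.make_two_class_image(0.4, 120.0, 0.0, seed=9)
        big = rescale(img, 2, channel_axis=2, order=0)
        m1 = np.ones(img.shape[:2], bool)
        m2 = np.ones(big.shape[:2], bool)
        c1, _ = hq.trichrome_fractions(img, m1)
        c2, _ = hq.trichrome_fractions(big, m2)
        assert c2 == pytest.approx(c1, rel=0.01)


class TestMorphometry:
    def test_circular_lumen_perimeter(self):
        media, lumen = synthetic.make_annulus_masks(100.0, 120.0)
        _, perimeter = hq.media_morphometry(media, lumen)
        assert perimeter == pytest.approx(2 * np.pi * 100, rel=0.01)

    def test_annulus_thickness(self):
        media, lumen = synthetic.make_annulus_masks(100.0, 120.0)
        thickness, _ = hq.media_morphometry(media, lumen)
        assert thickness == pytest.approx(20.0, abs=1.0)

    def test_ellipse_perimeter_vs_ramanujan(self):
        mask = np.zeros((300, 300), bool)
        rr, cc = ellipse(150, 150, 60, 100)
        mask[rr, cc] = True
        length = hq._contour_length_px(mask)
        a, b = 100.0, 60.0
        h = ((a - b) / (a + b)) ** 2
        ramanujan = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert length == pytest.approx(ramanujan, rel=0.01)

    def test_split_lumen_rejected(self):
        media, lumen = synthetic.make_annulus_masks(50.0, 70.0)
        lumen2 = lumen.copy()
        lumen2[:, lumen.shape[1] // 2] = False  # split into two parts
        with pytest.raises(ValueError, match="single component"):
            hq.media_morphometry(media, lumen2)


class TestPicrosirius:
    def test_all_orange(self):
        img = solid_color(40.0)
        mask = np.ones(img.shape[:2], bool)
        res = hq.picrosirius_classes(img, mask)
        assert res.pct_orange_thick == pytest.approx(100.0)
        assert res.pct_green_thin == pytest.approx(0.0)

    def test_black_image_no_birefringence(self):
        img = np.zeros((32, 32, 3))
        res = hq.picrosirius_classes(img, np.ones((32, 32), bool))
        assert res.birefringent_area_um2 == 0.0

    def test_mixed_70_30_with_jitter(self):
        img = synthetic.make_two_class_image(0.70, 40.0, 120.0, hue_jitter_deg=5.0, seed=4)
        res = hq.picrosirius_classes(img, np.ones(img.shape[:2], bool))
        assert res.pct_orange_thick == pytest.approx(70.0, abs=3.0)
        assert res.pct_green_thin == pytest.approx(30.0, abs=3.0)


class TestMaxEnt:
    def test_equals_bruteforce_on_random_histograms(self):
        """The vectorized Kapur threshold must pick the same split as the
        exhaustive entropy search on 100 random intensity samples."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            kind = rng.integers(3)
            if kind == 0:
                vals = rng.integers(0, 256, size=500)
            elif kind == 1:
                vals = np.clip(
                    np.concatenate(
                        [
                            rng.normal(rng.uniform(30, 90), 8, 400),
                            rng.normal(rng.uniform(140, 220), 12, 150),
                        ]
                    ),
                    0,
                    255,
                ).astype(int)
            else:
                vals = np.clip(rng.exponential(40, 600), 0, 255).astype(int)
            if vals.min() == vals.max():
                continue
            edges = np.arange(vals.min() - 0.5, vals.max() + 1.5)
            counts, _ = np.histogram(vals, bins=edges)
            t_oracle = kapur_bruteforce(counts)
            expected = edges[t_oracle + 1]
            assert hq.maxent_threshold(vals) == pytest.approx(expected)

    def test_two_delta_histogram(self):
        vals = np.array([10] * 900 + [200] * 100)
        t = hq.maxent_threshold(vals)
        assert 10 < t < 200
        img = vals.reshape(10, 100).astype(float)
        density = hq.if_intensity(img, np.ones((10, 100), bool), mode="maxent")
        assert density == pytest.approx(200 * 100)

    def test_single_valued_histogram_rejected(self):
        with pytest.raises(ValueError):
            hq.maxent_threshold(np.full(100, 7))


class TestIfIntensity:
    def test_mean_mode(self):
        img = np.full((16, 16), 100.0)
        assert hq.if_intensity(img, np.ones((16, 16), bool)) == pytest.approx(100.0)

    def test_control_normalization_identity(self):
        values = np.array([0.8, 1.0, 1.3, 2.0, 2.2, 2.5])
        groups = np.array(["ctrl", "ctrl", "ctrl", "mut", "mut", "mut"])
        norm = hq.normalize_to_control(values, groups, "ctrl")
        assert np.median(norm[groups == "ctrl"]) == pytest.approx(1.0)

    def test_unknown_control_rejected(self):
        with pytest.raises(ValueError):
            hq.normalize_to_control([1.0, 2.0], ["a", "a"], "b")


class TestShgTexture:
    def test_symmetric_two_point_skewness_zero(self):
        vals = np.tile([10.0, 20.0], 200).reshape(20, 20)
        tex = hq.shg_texture(vals, threshold=15.0)
        assert tex.skewness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_three(self):
        rng = np.random.default_rng(123)
        img = rng.normal(100.0, 10.0, 10**6).reshape(1000, 1000)
        tex = hq.shg_texture(img, threshold=100.0)
        assert tex.kurtosis == pytest.approx(3.0, abs=0.1)

    def test_exponential_skewness_two(self):
        rng = np.random.default_rng(7)
        img = rng.exponential(10.0, 10**6).reshape(1000, 1000)
        tex = hq.shg_texture(img, threshold=10.0)
        assert tex.skewness == pytest.approx(2.0, abs=0.05)

    def test_signal_amount_and_density(self):
        img = np.zeros((10, 10))
        img[0, :5] = 200.0
        img[1, 0] = 100.0
        tex = hq.shg_texture(img, threshold=50.0)
        assert tex.signal_area_px == 6
        assert tex.density == pytest.approx((5 * 200 + 100) / 6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hq.shg_texture(np.full((8, 8), 5.0))


class TestNuclei:
    def test_planted_disks_counted(self):
        img = synthetic.make_nuclei_image(7, seed=5)
        assert hq.count_nuclei(img, min_area_px=10) == 7

    def test_empty_image_zero(self):
        assert hq.count_nuclei(np.zeros((64, 64)), min_area_px=10) == 0

    def test_touching_pair_split_by_watershed(self):
        img = np.zeros((64, 64))
        for center in ((30, 25), (30, 34)):
            rr, cc = draw_disk(center, 6)
            img[rr, cc] = 200.0
        assert hq.count_nuclei(img, min_area_px=10) == 1
        assert hq.count_nuclei(img, min_area_px=10, split_touching=True) == 2
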