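"""Elastin rectilinearity: preprocessing, skeleton branches and the ratio."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.transform import rotate

from vasomech import synthetic, waviness

from conftest import straight_line_mask


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        img = np.full((64, 64), 37.0)
        out = waviness.preprocess(img, median_radius_px=1, ball_radius_px=10)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_hot_pixel_removed_by_median(self):
        img = np.zeros((32, 32))
        img[16, 16] = 255.0
        out = waviness.preprocess(img, median_radius_px=1, ball_radius_px=10)
        assert out[16, 16] == 0.0

    def test_gradient_background_flattened(self):
        """A bright fiber on a smooth gradient: after subtraction the
        background residual is < 5% of the fiber amplitude."""
        h, w = 64, 128
        background = np.linspace(0, 40, w)[None, :] * np.ones((h, 1))
        img = background.copy()
        img[30:33, 10:118] += 100.0
        out = waviness.preprocess(img, median_radius_px=1, ball_radius_px=15)
        bg_region = out[5:20, :]
        assert bg_region.max() < 0.05 * 100.0

    def test_oversized_ball_rejected(self):
        with pytest.raises(ValueError):
            waviness.preprocess(np.zeros((32, 32)), 1, 40)


class TestSegment:
    def test_two_level_image(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:20, 5:25] = 255
        for method in ("otsu", 100.0):
            mask = waviness.segment(img, method=method)
            np.testing.assert_array_equal(mask, img > 0)

    def test_threshold_above_max_is_empty_error(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:20, 5:25] = 200
        with pytest.raises(ValueError, match="empty mask"):
            waviness.segment(img, method=255.0)

    def test_roi_restricts_mask(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[:, :] = 200
        mask = waviness.segment(img, roi=(0, 0, 16, 16), method=100.0)
        assert mask[:16, :16].all() and not mask[16:, :].any()

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            waviness.segment(np.zeros((32, 32)), roi=(0, 0, 40, 40))

    def test_synthetic_fibers_dice_at_snr5(self):
        spec = synthetic.FiberSpec(
            amplitude_um=8.0, thickness_px=5, n_fibers=3, snr=5.0, seed=11
        )
        img, _, _ = synthetic.make_fiber_image(spec)
        truth_spec = synthetic.FiberSpec(
            amplitude_um=8.0, thickness_px=5, n_fibers=3, snr=1e9, seed=11
        )
        truth_img, _, _ = synthetic.make_fiber_image(truth_spec)
        truth = truth_img > 0.5
        clean = waviness.preprocess(img, median_radius_px=1, ball_radius_px=25)
        mask = waviness.segment(clean, method="otsu")
        dice = 2 * np.count_nonzero(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.8


class TestSkeleton:
    def test_ribbon_thins_to_single_line(self):
        mask = straight_line_mask(length=100, thickness=5)
        skel = waviness.skeletonize_and_prune(mask, min_component_px=10)
        rows, cols = np.nonzero(skel)
        assert 90 <= skel.sum() <= 101
        assert np.ptp(rows) <= 1  # essentially horizontal

    def test_small_components_removed(self):
        mask = np.zeros((64, 600), dtype=bool)
        mask[10, 5:15] = True  # 10 px
        mask[40, 5:505] = True  # 500 px
        skel = waviness.skeletonize_and_prune(mask, min_component_px=50)
        assert not skel[10].any() and skel[40].any()

    def test_skeleton_subset_of_mask(self):
        spec = synthetic.FiberSpec(amplitude_um=10.0, thickness_px=5, seed=3)
        img, _, _ = synthetic.make_fiber_image(spec)
        mask = img > 0.5
        skel = waviness.skeletonize_and_prune(mask, min_component_px=30)
        assert not (skel & ~mask).any()


class TestBranchDecompose:
    def test_horizontal_line_length(self):
        skel = np.zeros((16, 120), dtype=bool)
        skel[8, 10:110] = True  # 100 px
        branches = waviness.branch_decompose(skel, pixel_size_um=1.0)
        assert len(branches) == 1
        assert branches[0].fiber_length_um == pytest.approx(99.0)
        assert branches[0].fiber_distance_um == pytest.approx(99.0)

    def test_diagonal_line_chain_length(self):
        skel = np.zeros((120, 120), dtype=bool)
        idx = np.arange(10, 110)
        skel[idx, idx] = True
        branches = waviness.branch_decompose(skel, length_method="chain")
        assert branches[0].fiber_length_um == pytest.approx(99 * np.sqrt(2))
        # polyline estimator agrees on an exactly straight diagonal
        poly = waviness.branch_decompose(skel, length_method="polyline")
        assert poly[0].fiber_length_um == pytest.approx(99 * np.sqrt(2))

    def test_l_shaped_path(self):
        skel = np.zeros((80, 80), dtype=bool)
        skel[10, 10:60] = True  # 50 px horizontal
        skel[10:60, 59] = True  # 50 px vertical sharing the corner
        branches = waviness.branch_decompose(skel, length_method="chain")
        total = sum(b.fiber_length_um for b in branches)
        assert total == pytest.approx(98.0, abs=1.5)
        chord = max(b.fiber_distance_um for b in branches)
        assert chord == pytest.approx(np.hypot(49, 49), rel=0.02)

    def test_pixel_size_scales_lengths(self):
        skel = np.zeros((16, 120), dtype=bool)
        skel[8, 10:110] = True
        b1 = waviness.branch_decompose(skel, pixel_size_um=1.0)[0]
        b2 = waviness.branch_decompose(skel, pixel_size_um=0.5)[0]
        assert b2.fiber_length_um == pytest.approx(b1.fiber_length_um / 2)

    def test_cycle_flagged_with_max_chord(self):
        from skimage.draw import circle_perimeter

        skel = np.zeros((64, 64), dtype=bool)
        rr, cc = circle_perimeter(32, 32, 15)
        skel[rr, cc] = True
        branches = waviness.branch_decompose(skel)
        cycles = [b for b in branches if b.is_cycle]
        assert cycles
        assert cycles[0].fiber_distance_um == pytest.approx(30.0, abs=1.5)


class TestRectilinearity:
    def test_straight_branch_is_exactly_one(self):
        skel = np.zeros((16, 120), dtype=bool)
        skel[8, 10:110] = True
        res = waviness.rectilinearity(waviness.branch_decompose(skel))
        assert res.rectilinearity == 1.0

    def test_half_circle_two_over_pi(self, half_circle_skeleton):
        res = waviness.rectilinearity(
            waviness.branch_decompose(half_circle_skeleton)
        )
        assert res.rectilinearity == pytest.approx(2 / np.pi, rel=0.02)

    def test_sinusoid_unit_peak_slope(self):
        """a = lambda/(2 pi) gives chord/arc ~ 0.822 (quadrature oracle)."""
        lam = 60.0
        a = lam / (2 * np.pi)
        oracle = synthetic.sine_rectilinearity(a, lam, 255.0)
        assert oracle == pytest.approx(0.822, abs=0.01)
        spec = synthetic.FiberSpec(
            amplitude_um=a, wavelength_um=lam, thickness_px=3,
            n_fibers=3, snr=50.0, seed=1,
        )
        img, truths, _ = synthetic.make_fiber_image(spec)
        res = waviness.measure_image(
            img, threshold="otsu", ball_radius_px=25, min_component_px=30
        )
        assert res.rectilinearity == pytest.approx(np.mean(truths), rel=0.02)

    def test_no_branches_rejected(self):
        with pytest.raises(ValueError):
            waviness.rectilinearity([])

    def test_rotation_invariance(self, half_circle_skeleton):
        base = waviness.rectilinearity(
            waviness.branch_decompose(half_circle_skeleton)
        ).rectilinearity
        img = half_circle_skeleton.astype(float)
        rotated = rotate(img, 30.0, resize=True, order=1) > 0.3
        skel = waviness.skeletonize_and_prune(rotated, min_component_px=10)
        rot = waviness.rectilinearity(waviness.branch_decompose(skel)).rectilinearity
        assert rot == pytest.approx(base, rel=0.02)

    def test_thickness_invariance(self):
        values = []
        for thickness in (3, 9):
            spec = synthetic.FiberSpec(
                amplitude_um=10.0, thickness_px=thickness,
                n_fibers=3, snr=50.0, seed=2,
            )
            img, _, _ = synthetic.make_fiber_image(spec)
            res = waviness.measure_image(
                img, threshold="otsu", ball_radius_px=25, min_component_px=30
            )
            values.append(res.rectilinearity)
        assert abs(values[0] - values[1]) / values[0] < 0.02

    def test_amplitude_sweep_monotone(self):
        """Measured rectilinearity decreases strictly with generated
        amplitude (Spearman rho = 1 against the inverted order)."""
        amplitudes = [0.0, 4.0, 8.0, 12.0, 16.0]
        measured = []
        for a in amplitudes:
            spec = synthetic.FiberSpec(
                amplitude_um=a, thickness_px=3, n_fibers=3, snr=50.0, seed=5
            )
            img, _, _ = synthetic.make_fiber_image(spec)
            res = waviness.measure_image(
                img, threshold="otsu", ball_radius_px=25, min_component_px=30
            )
            measured.append(res.rectilinearity)
        rho, _ = spearmanr(amplitudes, measured)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_recovery_within_003_at_snr5(self):
        for seed in (7, 8):
            spec = synthetic.FiberSpec(
                amplitude_um=10.0, thickness_px=3, n_fibers=3, snr=5.0, seed=seed
            )
            img, truths, _ = synthetic.make_fiber_image(spec)
            res = waviness.measure_image(
                img, threshold="otsu", ball_radius_px=25, min_component_px=30
            )
            assert abs(res.rectilinearity - np.mean(truths)) <= 0.03

    def test_ground_truth_monotone_in_amplitude(self):
        truths = [
            synthetic.sine_rectilinearity(a, 60.0, 240.0)
            for a in (0.0, 5.0, 10.0, 20.0)
        ]
        assert truths[0] == 1.0
        assert all(x > y for x, y in zip(truths, truths[1:]))
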