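import numpy as np
import pytest

from cxrdiff import metrics_cv as mc
from cxrdiff.types import LungBox


class TestIoU:
    def test_identical(self):
        b = LungBox(0, 10, 0, 10)
        assert mc.iou(b, b) == 1.0

    def test_disjoint(self):
        assert mc.iou(LungBox(0, 5, 0, 5), LungBox(6, 10, 6, 10)) == 0.0

    def test_half_overlap_third(self):
        a = LungBox(0, 10, 0, 10)
        b = LungBox(0, 10, 5, 15)
        assert mc.iou(a, b) == pytest.approx(1 / 3, abs=1e-15)

    def test_symmetry_and_bound(self, rng):
        for _ in range(20):
            t1, l1 = rng.integers(0, 20, 2)
            t2, l2 = rng.integers(0, 20, 2)
            a = LungBox(t1, t1 + int(rng.integers(1, 20)),
                        l1, l1 + int(rng.integers(1, 20)))
            b = LungBox(t2, t2 + int(rng.integers(1, 20)),
                        l2, l2 + int(rng.integers(1, 20)))
            assert mc.iou(a, b) == mc.iou(b, a)
            assert mc.iou(a, b) <= min(a.area, b.area) / max(a.area, b.area)

    def test_half_open_convention(self):
        # [0,1) x [0,1) is exactly one pixel
        assert LungBox(0, 1, 0, 1).area == 1
        # touching boxes share no pixels
        assert mc.iou(LungBox(0, 5, 0, 5), LungBox(0, 5, 5, 10)) == 0.0


class TestDetectionRate:
    def test_all_above(self):
        assert mc.detection_rate([0.9] * 10, 0.7) == 100.0

    def test_half(self):
        assert mc.detection_rate([0.8, 0.6], 0.7) == 50.0

    def test_zero_threshold(self):
        assert mc.detection_rate([0.1, 0.5], 0.0) == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mc.detection_rate([], 0.7)

    def test_sweep_monotone_nonincreasing(self, rng):
        ious = rng.uniform(0, 1, 50)
        curve = mc.detection_rate_sweep(ious, np.linspace(0, 1, 11))
        rates = [r for _, r in curve]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestPsnr:
    def test_mse_one_8bit(self):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = a.copy()
        b[:, :] = 1  # MSE exactly 1
        assert mc.psnr(a, b) == pytest.approx(20 * np.log10(255), abs=1e-4)
        assert mc.psnr(a, b) == pytest.approx(48.1308, abs=1e-4)

    def test_identical_infinite_sentinel(self):
        a = np.ones((8, 8))
        assert mc.psnr(a, a) == mc.PSNR_INF_SENTINEL

    def test_unit_mse_001(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # MSE = 0.01
        assert mc.psnr(a, b, peak=1.0) == pytest.approx(20.0, abs=1e-10)

    def test_decreasing_in_mse(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        p1 = mc.psnr(a, a + 0.01, peak=1.0)
        p2 = mc.psnr(a, a + 0.02, peak=1.0)
        assert p1 > p2

    def test_depth_mismatch_errors(self):
        with pytest.raises(ValueError, match="depth"):
            mc.psnr(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 4)))


class TestSsim:
    def test_identical_is_one(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        assert mc.ssim(a, a, peak=1.0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_below_one(self):
        a = np.full((32, 32), 0.4)
        b = a + 0.05
        v = mc.ssim(a, b, peak=1.0)
        assert v < 1.0

    def test_symmetric(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        assert mc.ssim(a, b, peak=1.0) == pytest.approx(
            mc.ssim(b, a, peak=1.0), abs=1e-12)


class TestNcc:
    def test_positive_affine(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        assert mc.ncc(a, 2 * a + 3) == pytest.approx(1.0, abs=1e-12)

    def test_negation(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        assert mc.ncc(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_bound(self):
        r = np.random.default_rng(0)
        a = r.uniform(0, 1, (100, 100))
        b = r.uniform(0, 1, (100, 100))
        assert abs(mc.ncc(a, b)) <= 0.05

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            mc.ncc(np.full((4, 4), 0.5), np.zeros((4, 4)) + 0.1)


class TestKfold:
    def test_2000_items_folds_of_400(self):
        plan = mc.kfold(2000, 5, seed=0)
        sizes = np.bincount(plan.assignment)
        assert np.array_equal(sizes, [400] * 5)

    def test_partition(self):
        plan = mc.kfold(103, 5, seed=1)
        seen = np.zeros(103, dtype=int)
        for train, test in plan.folds():
            assert len(np.intersect1d(train, test)) == 0
            seen[test] += 1
        assert np.all(seen == 1)
        sizes = np.bincount(plan.assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        a = mc.kfold(50, 5, seed=3)
        b = mc.kfold(50, 5, seed=3)
        assert np.array_equal(a.assignment, b.assignment)

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            mc.kfold(3, 5)


class TestAuc:
    def test_perfect_separation(self):
        labels = np.array([[0], [0], [1], [1]])
        scores = np.array([[0.1], [0.2], [0.8], [0.9]])
        per_class, macro = mc.evaluate_auc(scores, labels)
        assert per_class[0] == 1.0 and macro == 1.0

    def test_random_scores_near_half(self):
        r = np.random.default_rng(0)
        labels = r.integers(0, 2, size=(1000, 1))
        scores = r.uniform(size=(1000, 1))
        _, macro = mc.evaluate_auc(scores, labels)
        assert abs(macro - 0.5) <= 0.05

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=(50, 1))
        labels[0], labels[1] = 0, 1
        scores = rng.uniform(size=(50, 1))
        _, m1 = mc.evaluate_auc(scores, labels)
        _, m2 = mc.evaluate_auc(np.exp(3 * scores), labels)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_single_valued_class_excluded_with_warning(self):
        labels = np.array([[0, 1], [0, 0], [0, 1], [0, 0]])
        scores = np.array([[0.5, 0.9], [0.5, 0.1], [0.5, 0.8], [0.5, 0.2]])
        with pytest.warns(UserWarning, match="single label value"):
            per_class, macro = mc.evaluate_auc(scores, labels)
        assert np.isnan(per_class[0]) and macro == 1.0


class TestBruteForceAgreement:
    """Independent loop-based oracles on random 16x16 images."""

    def test_psnr_oracle(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        b = rng.uniform(0, 1, (16, 16))
        mse = sum((a[i, j] - b[i, j]) ** 2 for i in range(16)
                  for j in range(16)) / 256
        assert mc.psnr(a, b, peak=1.0) == pytest.approx(
            10 * np.log10(1.0 / mse), abs=1e-10)

    def test_ncc_oracle(self, rng):
        a = rng.uniform(0, 1, (16, 16)).ravel()
        b = rng.uniform(0, 1, (16, 16)).ravel()
        am, bm = a.mean(), b.mean()
        num = sum((x - am) * (y - bm) for x, y in zip(a, b))
        den = np.sqrt(sum((x - am) ** 2 for x in a)
                      * sum((y - bm) ** 2 for y in b))
        assert mc.ncc(a.reshape(16, 16), b.reshape(16, 16)) == pytest.approx(
            num / den, abs=1e-10)

    def test_iou_pixel_count_oracle(self, rng):
        a = LungBox(2, 9, 3, 12)
        b = LungBox(5, 14, 0, 8)
        grid_a = np.zeros((20, 20), dtype=bool)
        grid_b = np.zeros((20, 20), dtype=bool)
        grid_a[a.top:a.bottom, a.left:a.right] = True
        grid_b[b.top:b.bottom, b.left:b.right] = True
        expected = (grid_a & grid_b).sum() / (grid_a | grid_b).sum()
        assert mc.iou(a, b) == pytest.approx(expected, abs=1e-12)

    def test_ssim_oracle_uniform_window(self, rng):
        """Cross-check against an explicit per-window implementation with
        the same Gaussian weights as the production path."""
        from scipy.ndimage import gaussian_filter

        a = rng.uniform(0, 1, (24, 24))
        b = np.clip(a + rng.normal(0, 0.05, (24, 24)), 0, 1)
        c1 = (0.01 * 1.0) ** 2
        c2 = (0.03 * 1.0) ** 2
        trunc = (11 - 1) / 2 / 1.5
        g = lambda x: gaussian_filter(x, 1.5, truncate=trunc, mode="reflect")
        mu_a, mu_b = g(a), g(b)
        va = g(a * a) - mu_a ** 2
        vb = g(b * b) - mu_b ** 2
        cov = g(a * b) - mu_a * mu_b
        smap = (((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
        pad = 5
        expected = smap[pad:-pad, pad:-pad].mean()
        assert mc.ssim(a, b, peak=1.0) == pytest.approx(expected, abs=1e-7)
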