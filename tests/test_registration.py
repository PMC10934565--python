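import numpy as np
import pytest

from cxrdiff import phantom, registration as reg
from cxrdiff.types import DisplacementField


def smooth_image(rng, n=48):
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.uniform(0, 1, (n, n)), 3.0)


class TestWarp:
    def test_zero_field_identity(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out = reg.warp(img, np.zeros((2, 16, 16)))
        np.testing.assert_array_equal(out, img)

    def test_integer_shift_exact(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        fld = np.zeros((2, 16, 16))
        fld[1] = 1.0
        out = reg.warp(img, fld)
        np.testing.assert_array_equal(out[:, :-1], img[:, 1:])

    def test_half_pixel_shift_neighbor_average(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        fld = np.zeros((2, 16, 16))
        fld[1] = 0.5
        out = reg.warp(img, fld)
        np.testing.assert_allclose(out[:, :-1],
                                   (img[:, :-1] + img[:, 1:]) / 2,
                                   atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reg.warp(np.zeros((4, 4)), np.zeros((2, 5, 5)))

    def test_displacement_field_type_accepted(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        out = reg.warp(img, DisplacementField.zero((8, 8)))
        np.testing.assert_array_equal(out, img)


class TestLocalNcc:
    def test_identical_is_one(self, rng):
        a = smooth_image(rng)
        assert reg.local_ncc(a, a, radius=3) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        a = smooth_image(rng)
        assert reg.local_ncc(a, 1.7 * a + 0.2, radius=3) == pytest.approx(
            1.0, abs=1e-9)

    def test_negation_gives_minus_one(self, rng):
        a = smooth_image(rng)
        assert reg.local_ncc(a, -a, radius=3) == pytest.approx(-1.0, abs=1e-9)

    def test_constant_images_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            reg.local_ncc(np.full((8, 8), 0.5), np.full((8, 8), 0.5))


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        hist, _ = np.histogram(a, bins=32)
        p = hist / hist.sum()
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert reg.mutual_information(a, a, bins=32) == pytest.approx(
            entropy, abs=1e-10)

    def test_independent_noise_near_zero(self):
        r = np.random.default_rng(0)
        a = r.uniform(0, 1, (100, 100))
        b = r.uniform(0, 1, (100, 100))
        assert reg.mutual_information(a, b, bins=16) <= 0.05

    def test_symmetric(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        assert reg.mutual_information(a, b) == pytest.approx(
            reg.mutual_information(b, a), abs=1e-12)


class TestClassicalRegister:
    def test_identical_images_keep_zero_field(self, rng):
        img = smooth_image(rng, 64)
        res = reg.classical_register(
            img, img, reg.ClassicalRegConfig(iterations=20,
                                             pyramid_levels=1))
        assert np.abs(res.field.vectors).mean() <= 0.1
        # the returned field is the best seen, so its metric cannot be
        # below the starting value
        assert max(res.metric_trace) >= res.metric_trace[0]

    def test_translation_recovery(self):
        spec_rng = np.random.default_rng(3)
        spec = phantom.random_pair_spec(spec_rng, image_size=96,
                                        noise_sigma=0.0, max_deformation=0.0,
                                        lesion_prob=0.0, new_lesion_prob=0.0)
        from dataclasses import replace

        spec = replace(spec, global_shift=(2.0, 0.0), gain=1.0, offset=0.0)
        pre, post, truth = phantom.generate_pair(spec)
        res = reg.classical_register(pre, post)
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(truth.lung_mask, iterations=4)
        err = np.hypot(*(res.field.vectors - truth.true_field.vectors))
        assert err[interior].mean() <= 0.5

    def test_best_so_far_metric_nondecreasing(self, rng):
        img = smooth_image(rng, 48)
        moved = reg.warp(img, np.full((2, 48, 48), 1.0))
        res = reg.classical_register(
            moved, img, reg.ClassicalRegConfig(iterations=15,
                                               pyramid_levels=1))
        best = np.maximum.accumulate(res.metric_trace)
        assert np.all(np.diff(best) >= -1e-12)

    def test_mutual_information_metric_runs(self, rng):
        img = smooth_image(rng, 48)
        moved = reg.warp(img, np.full((2, 48, 48), 1.5))
        res = reg.classical_register(
            moved, img, reg.ClassicalRegConfig(
                metric="mutual_information", iterations=25,
                pyramid_levels=1))
        assert res.metric_trace[-1] >= res.metric_trace[0] - 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reg.classical_register(np.zeros((8, 8)), np.zeros((9, 9)))


class TestVoxelMorphNet:
    TINY = reg.VoxelMorphConfig(enc_channels=(4, 8, 8, 8),
                                dec_channels=(8, 8, 8, 8),
                                extra_channels=(4,), epochs=2,
                                batch_size=2, lr=1e-3, seed=0)

    def test_output_shape(self, rng):
        model = reg.VoxelMorphNet(self.TINY)
        fld = model.predict_field(rng.uniform(0, 1, (32, 32)),
                                  rng.uniform(0, 1, (32, 32)))
        assert fld.vectors.shape == (2, 32, 32)

    def test_untrained_zero_field(self, rng):
        model = reg.VoxelMorphNet(self.TINY)
        fld = model.predict_field(rng.uniform(0, 1, (32, 32)),
                                  rng.uniform(0, 1, (32, 32)))
        assert not fld.vectors.any()

    def test_size_not_divisible_by_16(self, rng):
        model = reg.VoxelMorphNet(self.TINY)
        with pytest.raises(ValueError, match="divisible"):
            model.predict_field(np.zeros((30, 30)), np.zeros((30, 30)))

    def test_training_decreases_loss_and_is_reproducible(self, rng):
        pairs = []
        for seed in range(4):
            spec = phantom.random_pair_spec(
                np.random.default_rng(seed), image_size=32,
                noise_sigma=0.01, max_deformation=1.5)
            pre, post, _ = phantom.generate_pair(spec)
            pairs.append((pre, post))
        log1, log2 = [], []
        reg.train_voxelmorph(pairs, self.TINY, log=log1)
        reg.train_voxelmorph(pairs, self.TINY, log=log2)
        assert log1[-1] < log1[0]
        assert log1 == log2

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            reg.train_voxelmorph([], self.TINY)


class TestRegisterOrchestrator:
    def test_identity_pair_no_degradation(self, identity_pair):
        _, pre, post, _ = identity_pair
        res = reg.register(pre, post, method="classical",
                           config=reg.ClassicalRegConfig(iterations=10,
                                                         pyramid_levels=1))
        assert (res.metrics_after["ssim"]
                >= res.metrics_before["ssim"] - 0.01)

    def test_deformed_pair_improves_all_indices(self, clean_pair):
        _, pre, post, _ = clean_pair
        res = reg.register(pre, post, method="classical",
                           config=reg.ClassicalRegConfig(iterations=60))
        assert res.metrics_after["psnr"] > res.metrics_before["psnr"]
        assert res.metrics_after["ssim"] > res.metrics_before["ssim"]
        assert res.metrics_after["ncc"] > res.metrics_before["ncc"]

    def test_learned_without_model_errors(self, rng):
        with pytest.raises(ValueError, match="model"):
            reg.register(rng.uniform(0, 1, (32, 32)),
                         rng.uniform(0, 1, (32, 32)), method="learned")

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError, match="method"):
            reg.register(np.zeros((8, 8)), np.zeros((8, 8)), method="rigid")
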