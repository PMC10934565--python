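import numpy as np
import pytest

from cxrdiff import nn, phantom, seg_detector as sd
from cxrdiff.metrics_cv import iou
from cxrdiff.types import LungBox

TINY = sd.desk_config(image_size=64, stem_channels=4,
                      stage_channels=(8, 8, 8, 8),
                      level_strides=(32,), fpn_channels=8, epochs=1,
                      batch_size=2)


class TestFocalLoss:
    def test_perfect_prediction_vanishes(self):
        assert sd.focal_loss(np.array([1.0 - 1e-9]), np.array([1])) < 1e-6

    def test_gamma_zero_reduces_to_half_bce(self, rng):
        p = rng.uniform(0.05, 0.95, 20)
        t = rng.integers(0, 2, 20)
        fl = sd.focal_loss(p, t, alpha=0.5, gamma=0.0)
        bce = -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert fl == pytest.approx(0.5 * bce, rel=1e-9)

    def test_printed_value(self):
        v = sd.focal_loss(np.array([0.9]), np.array([1]),
                          alpha=0.25, gamma=2.0)
        assert v == pytest.approx(0.25 * 0.01 * -np.log(0.9), rel=1e-9)
        assert v == pytest.approx(2.634e-4, rel=1e-3)

    def test_nonnegative_and_monotone(self, rng):
        ps = np.linspace(0.01, 0.99, 50)
        losses = [sd.focal_loss(np.array([p]), np.array([1])) for p in ps]
        assert min(losses) >= 0
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_extreme_probabilities_clamped(self):
        assert np.isfinite(sd.focal_loss(np.array([0.0, 1.0]),
                                         np.array([1, 0])))


class TestAssignAnchors:
    def test_identical_anchor_positive_zero_target(self):
        truth = LungBox(10, 50, 20, 60)
        anchors = np.array([[10, 50, 20, 60], [200, 240, 200, 240]],
                           dtype=float)
        cls, regs = sd.assign_anchors(anchors, truth, 0.5, 0.4)
        assert cls[0] == 1.0
        np.testing.assert_allclose(regs[0], 0.0, atol=1e-12)

    def test_disjoint_anchor_negative(self):
        truth = LungBox(10, 50, 20, 60)
        anchors = np.array([[100, 140, 100, 140]], dtype=float)
        cls, _ = sd.assign_anchors(anchors, truth, 0.5, 0.4)
        # disjoint but also best-IoU anchor; add a second better one
        anchors = np.array([[100, 140, 100, 140], [10, 50, 20, 60]],
                           dtype=float)
        cls, _ = sd.assign_anchors(anchors, truth, 0.5, 0.4)
        assert cls[0] == 0.0 and cls[1] == 1.0

    def test_iou_55_is_positive(self):
        truth = LungBox(0, 100, 0, 100)
        # anchor [0,100)x[0,55) sits inside truth: IoU = 5500/10000 = 0.55
        anchors = np.array([[0, 100, 0, 55]], dtype=float)
        got = sd._pairwise_iou(anchors, truth)[0]
        assert got == pytest.approx(0.55, abs=1e-12)
        cls, _ = sd.assign_anchors(anchors, truth, 0.5, 0.4)
        assert cls[0] == 1.0

    def test_between_thresholds_ignored(self):
        truth = LungBox(0, 100, 0, 100)
        anchors = np.array([[0, 100, 0, 45], [0, 100, 0, 100]], dtype=float)
        cls, _ = sd.assign_anchors(anchors, truth, 0.5, 0.45 / 1.55 + 0.01)
        assert cls[0] == -1.0  # IoU = 45/155 = 0.29.. between thresholds

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            sd.assign_anchors(np.zeros((1, 4)), LungBox(0, 2, 0, 2),
                              0.3, 0.5)

    def test_encode_decode_round_trip(self, rng):
        anchors = np.array([[10.0, 90.0, 20.0, 80.0]])
        box = LungBox(15, 85, 25, 75)
        deltas = sd._encode(anchors, box)
        back = sd._decode(anchors, deltas)[0]
        np.testing.assert_allclose(
            back, [box.top, box.bottom, box.left, box.right], atol=1e-9)


class TestDecodeAndNms:
    CFG = sd.desk_config(score_threshold=0.3, box_voting=False)

    def _identity_deltas(self, n):
        return np.zeros((n, 4))

    def test_duplicate_suppressed(self):
        anchors = np.array([[10, 50, 10, 50], [10, 50, 10, 50]], dtype=float)
        dets = sd.decode_and_nms(np.array([0.9, 0.8]),
                                 self._identity_deltas(2), anchors, self.CFG)
        assert len(dets) == 1
        assert dets[0].score == pytest.approx(0.9)

    def test_disjoint_both_survive(self):
        anchors = np.array([[10, 30, 10, 30], [60, 90, 60, 90]], dtype=float)
        dets = sd.decode_and_nms(np.array([0.7, 0.6]),
                                 self._identity_deltas(2), anchors, self.CFG)
        assert len(dets) == 2
        assert dets[0].score >= dets[1].score

    def test_suppression_triangle(self):
        # A overlaps B heavily, C is disjoint from A: survivors {A, C}
        anchors = np.array([[10, 50, 10, 50],
                            [12, 52, 12, 52],
                            [70, 100, 70, 100]], dtype=float)
        dets = sd.decode_and_nms(np.array([0.9, 0.8, 0.7]),
                                 self._identity_deltas(3), anchors, self.CFG)
        boxes = [d.box.as_tuple() for d in dets]
        assert len(dets) == 2
        assert (70, 100, 70, 100) in boxes

    def test_no_detection_above_threshold(self):
        anchors = np.array([[10, 50, 10, 50]], dtype=float)
        dets = sd.decode_and_nms(np.array([0.1]), self._identity_deltas(1),
                                 anchors, self.CFG)
        assert dets == []

    def test_nms_pairwise_iou_below_threshold(self, rng):
        anchors = sd._anchor_grid(self.CFG)
        scores = rng.uniform(0, 1, len(anchors))
        deltas = rng.normal(0, 0.1, (len(anchors), 4))
        dets = sd.decode_and_nms(scores, deltas, anchors, self.CFG)
        for i, a in enumerate(dets):
            for b in dets[i + 1:]:
                assert iou(a.box, b.box) < self.CFG.nms_iou + 0.1


class TestModel:
    def test_forward_shapes(self, rng):
        model = sd.DetectorModel(TINY)
        cls, reg_out = model(nn.Tensor(
            rng.uniform(0, 1, (2, 1, 64, 64)).astype(np.float32)))
        n_anchors = len(sd._anchor_grid(TINY))
        assert cls.shape == (2, n_anchors)
        assert reg_out.shape == (2, 4 * n_anchors)

    def test_loss_decreases_after_one_step(self, rng):
        spec = phantom.random_pair_spec(np.random.default_rng(0),
                                        image_size=64)
        img, truth = phantom.generate_phantom(spec)
        model = sd.DetectorModel(TINY)
        anchors = sd._anchor_grid(TINY)
        images = img[None].astype(np.float32)
        opt = nn.Adam(model.parameters(), lr=1e-4)
        first = sd.detector_loss(model, images, [truth.lung_box], anchors)
        first.backward()
        opt.step()
        second = sd.detector_loss(model, images, [truth.lung_box], anchors)
        assert float(second.data) < float(first.data)

    def test_train_empty_dataset(self):
        with pytest.raises(ValueError):
            sd.train_detector([], TINY)

    def test_untrained_high_threshold_errors(self, rng):
        model = sd.DetectorModel(
            sd.desk_config(image_size=64, stem_channels=4,
                           stage_channels=(8, 8, 8, 8), level_strides=(32,),
                           fpn_channels=8, score_threshold=0.99))
        noise = rng.uniform(0, 1, (64, 64))
        with pytest.raises(ValueError, match="score_threshold"):
            sd.detect_lung(noise, model)

    def test_detect_box_within_bounds(self, rng):
        from dataclasses import replace

        model = sd.DetectorModel(replace(TINY, score_threshold=1e-4))
        spec = phantom.random_pair_spec(np.random.default_rng(1),
                                        image_size=64)
        img, _ = phantom.generate_phantom(spec)
        box = sd.detect_lung(img, model)  # untrained, low threshold
        assert 0 <= box.top < box.bottom <= 64
        assert 0 <= box.left < box.right <= 64

    def test_save_load_round_trip(self, tmp_path, rng):
        model = sd.DetectorModel(TINY)
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        before = model(nn.Tensor(img[None, None]))[0].data
        sd.save_detector(model, tmp_path / "m.ckpt")
        loaded = sd.load_detector(tmp_path / "m.ckpt")
        after = loaded(nn.Tensor(img[None, None]))[0].data
        np.testing.assert_array_equal(before, after)


def test_scheduler_behaviour_in_training(rng):
    """Plateau scheduler drops lr to a tenth after `patience` bad epochs."""
    data = []
    for seed in range(6):
        spec = phantom.random_pair_spec(np.random.default_rng(seed),
                                        image_size=64)
        img, truth = phantom.generate_phantom(spec)
        data.append((img, truth.lung_box))
    log = {}
    cfg = sd.desk_config(image_size=64, stem_channels=4,
                         stage_channels=(8, 8, 8, 8), level_strides=(32,),
                         fpn_channels=8, epochs=6, batch_size=2,
                         lr=1e-4, patience=3)
    sd.train_detector(data, cfg, log=log)
    lrs = log["lr"]
    assert lrs[0] in (1e-4, 1e-5)
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))
    # any reduction is exactly a factor of the configured decay
    for a, b in zip(lrs, lrs[1:]):
        if b < a:
            assert b == pytest.approx(a * 0.1)
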