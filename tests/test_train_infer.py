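"""Assignment, ProbIoU loss, training loop contracts and inference."""

import math

import numpy as np
import pytest

from oeyolo.geometry import Detection, OrientedBox, polygon_iou, prob_iou
from oeyolo.network import BackboneSpec, ModelConfig, build_oe_yolo
from oeyolo.nn import Tensor
from oeyolo.train_infer import (
    TrainConfig,
    _probiou_vec,
    assign_targets,
    build_center_assignment,
    detect,
    detection_loss,
    load_checkpoint,
    save_checkpoint,
    train,
)

from conftest import random_box

TINY = ModelConfig(
    backbone=BackboneSpec(width_mult=0.125, depth_mult=0.2, stochastic_depth=0.0),
    neck_channels=(16, 24, 32), reg_max=8, seed=0,
)


def tiny_model():
    return build_oe_yolo(TINY)


def toy_samples(rng, n, size=96, objects=3):
    out = []
    for _ in range(n):
        img = (rng.random((size, size, 3)) * 255).astype(np.uint8)
        boxes = [
            OrientedBox(
                float(rng.uniform(20, size - 20)), float(rng.uniform(20, size - 20)),
                float(rng.uniform(20, 40)), float(rng.uniform(5, 10)),
                float(rng.uniform(-1.2, 1.2)),
            )
            for _ in range(objects)
        ]
        out.append((img, boxes))
    return out


class TestTrainConfig:
    def test_defaults_follow_reference_protocol(self):
        cfg = TrainConfig()
        assert cfg.epochs == 110
        assert cfg.initial_lr == 0.01
        assert cfg.weight_decay == 0.001
        assert cfg.image_size == 608
        assert cfg.assignment_iou_pos == 0.7
        assert cfg.nms_iou == 0.35

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(image_size=100)


class TestAssignTargets:
    def test_high_iou_positive(self):
        gt = OrientedBox(50, 50, 40, 10, 0.2)
        near = OrientedBox(51, 50, 40, 10, 0.2)
        assert polygon_iou(near, gt) >= 0.7
        a = assign_targets([near], [gt], 0.7)
        assert a.positive[0] and a.matched_gt[0] == 0

    def test_mid_iou_negative(self):
        gt = OrientedBox(50, 50, 40, 10, 0.0)
        off = OrientedBox(50, 55, 40, 10, 0.0)
        assert polygon_iou(off, gt) < 0.7
        a = assign_targets([off], [gt], 0.7)
        assert not a.positive[0] and a.matched_gt[0] == -1

    def test_identical_candidate_matched(self):
        gt = OrientedBox(10, 10, 8, 4, 0.5)
        a = assign_targets([gt], [OrientedBox(100, 100, 8, 4, 0), gt], 0.7)
        assert a.positive[0] and a.matched_gt[0] == 1

    def test_empty_gts_all_negative(self):
        a = assign_targets([OrientedBox(5, 5, 4, 2, 0)], [], 0.7)
        assert not a.positive.any()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            assign_targets([], [], 0.0)


class TestProbIoUAutograd:
    def test_matches_geometry_implementation(self, rng):
        boxes_a = [random_box(rng, 50, 4, 60) for _ in range(30)]
        boxes_b = [random_box(rng, 50, 4, 60) for _ in range(30)]
        pred = {
            k: Tensor(np.array([getattr(b, k2) for b in boxes_a], dtype=np.float64))
            for k, k2 in zip(("cx", "cy", "w", "h", "theta"),
                             ("cx", "cy", "w", "h", "theta"))
        }
        gt = {
            k: np.array([getattr(b, k) for b in boxes_b])
            for k in ("cx", "cy", "w", "h", "theta")
        }
        vec = _probiou_vec(pred, gt).data
        ref = np.array([prob_iou(a, b) for a, b in zip(boxes_a, boxes_b)])
        np.testing.assert_allclose(vec, ref, atol=1e-5)

    def test_gradients_finite_and_nonzero(self, rng):
        pred = {k: Tensor(np.array([v]), requires_grad=True)
                for k, v in zip(("cx", "cy", "w", "h", "theta"),
                                (10.0, 10.0, 30.0, 8.0, 0.3))}
        gt = {k: np.array([v]) for k, v in zip(("cx", "cy", "w", "h", "theta"),
                                               (14.0, 12.0, 26.0, 6.0, 0.6))}
        loss = (1.0 - _probiou_vec(pred, gt)).sum()
        loss.backward()
        for k, t in pred.items():
            assert np.isfinite(t.grad).all()
            assert abs(float(t.grad[0])) > 0, f"zero gradient for {k}"


class TestCenterAssignment:
    def test_every_gt_receives_a_positive(self, rng):
        gts = [[random_box(rng, 100, 16, 60).translated(150, 150) for _ in range(5)]]
        shapes = [(38, 38), (19, 19), (10, 10)]
        per_level, cls_t = build_center_assignment(gts, shapes, (8, 16, 32))
        assigned = set()
        for lvl in per_level:
            assigned.update(lvl["gt"].tolist())
        assert assigned == set(range(5))

    def test_positive_centers_inside_gt(self):
        gt = OrientedBox(100, 100, 60, 16, 0.5)
        per_level, _ = build_center_assignment([[gt]], [(38, 38), (19, 19), (10, 10)],
                                               (8, 16, 32))
        ct, st = math.cos(gt.theta), math.sin(gt.theta)
        found = 0
        for lvl, stride in zip(per_level, (8, 16, 32)):
            for yy, xx in zip(lvl["yi"], lvl["xi"]):
                px, py = (xx + 0.5) * stride - gt.cx, (yy + 0.5) * stride - gt.cy
                u = px * ct + py * st
                v = -px * st + py * ct
                assert abs(u) <= gt.w / 2 + 1e-9 and abs(v) <= gt.h / 2 + 1e-9
                found += 1
        assert found > 0

    def test_tiny_box_falls_back_to_center_cell(self):
        gt = OrientedBox(100, 100, 3, 1, 0.0)  # smaller than any cell
        per_level, _ = build_center_assignment([[gt]], [(38, 38), (19, 19), (10, 10)],
                                               (8, 16, 32))
        assert len(per_level[0]["bi"]) == 1
        assert (per_level[0]["yi"][0], per_level[0]["xi"][0]) == (12, 12)


class TestDetectionLoss:
    def _outputs_and_assignment(self, rng, model, gts):
        img = Tensor(rng.random((1, 3, 96, 96)).astype(np.float32))
        outs = model(img)
        shapes = [(o[0].shape[2], o[0].shape[3]) for o in outs]
        asg = build_center_assignment([gts], shapes, model.strides)
        return outs, asg

    def test_nonnegative_and_box_weight_linearity(self, rng):
        model = tiny_model().train()
        gts = [OrientedBox(48, 48, 30, 8, 0.4)]
        outs, asg = self._outputs_and_assignment(rng, model, gts)
        t1, b1, c1 = detection_loss(outs, asg, gts, model.strides, 8, False, 7.5, 1.0)
        t2, b2, c2 = detection_loss(outs, asg, gts, model.strides, 8, False, 15.0, 1.0)
        assert float(t1.data) >= 0 and float(b1.data) >= 0 and float(c1.data) >= 0
        assert float(b2.data) == pytest.approx(float(b1.data), rel=1e-6)
        contribution1 = float(t1.data) - float(c1.data)
        contribution2 = float(t2.data) - float(c2.data)
        assert contribution2 == pytest.approx(2 * contribution1, rel=1e-5)

    def test_no_positives_box_term_zero(self, rng):
        model = tiny_model().train()
        outs, asg = self._outputs_and_assignment(rng, model, [])
        total, box_t, cls_t = detection_loss(outs, asg, [], model.strides, 8, False)
        assert float(box_t.data) == 0.0
        assert float(cls_t.data) > 0.0


class TestTrainLoop:
    def test_one_epoch_log_and_reproducible_loss(self, rng):
        samples = toy_samples(rng, 4)
        cfg = TrainConfig(epochs=1, image_size=96, batch_size=4, augmentation=None,
                          val_interval=0)
        _, log1 = train(build_oe_yolo(TINY), samples, cfg)
        _, log2 = train(build_oe_yolo(TINY), samples, cfg)
        assert len(log1) == 1
        assert np.isfinite(log1[0]["loss"])
        assert log1[0]["loss"] == pytest.approx(log2[0]["loss"], rel=1e-5)

    def test_lr_schedule_decays(self, rng):
        samples = toy_samples(rng, 2)
        cfg = TrainConfig(epochs=3, image_size=96, batch_size=2, augmentation=None,
                          val_interval=0)
        _, log = train(build_oe_yolo(TINY), samples, cfg)
        assert log[-1]["lr"] < log[0]["lr"]
        assert log[0]["lr"] == pytest.approx(cfg.initial_lr)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_oe_yolo(TINY), [], TrainConfig(epochs=1, image_size=96))

    def test_loss_decreases_on_fixed_batch(self, rng):
        samples = toy_samples(rng, 4, objects=2)
        cfg = TrainConfig(epochs=8, image_size=96, batch_size=4, augmentation=None,
                          val_interval=0, initial_lr=0.005)
        _, log = train(build_oe_yolo(TINY), samples, cfg)
        assert log[-1]["loss"] < log[0]["loss"]


class TestDetect:
    def test_impossible_confidence_gives_empty(self, rng):
        model = tiny_model()
        img = (rng.random((96, 96, 3)) * 255).astype(np.uint8)
        assert detect(model, img, conf_thr=1.0) == []

    def test_survivors_respect_nms_threshold(self, rng):
        model = tiny_model()
        img = (rng.random((96, 96, 3)) * 255).astype(np.uint8)
        dets = detect(model, img, conf_thr=0.05, nms_iou=0.35)
        for i, a in enumerate(dets):
            for b in dets[i + 1:]:
                assert polygon_iou(a.box, b.box) <= 0.35 + 1e-9

    def test_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            detect(tiny_model(), np.zeros((16, 16, 3), np.uint8))

    def test_letterbox_scaling_back_to_source(self, rng):
        model = tiny_model()
        img = (rng.random((192, 192, 3)) * 255).astype(np.uint8)
        dets = detect(model, img, conf_thr=0.05, image_size=96)
        for d in dets:
            assert -96 < d.box.cx < 300 and -96 < d.box.cy < 300


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, rng, tmp_path):
        model = tiny_model()
        x = Tensor(rng.random((1, 3, 96, 96)).astype(np.float32))
        model.eval()
        ref = model(x)[0][0].data
        save_checkpoint(model, tmp_path / "w.npz")
        again = load_checkpoint(tmp_path / "w.npz")
        again.eval()
        np.testing.assert_allclose(again(x)[0][0].data, ref, atol=1e-6)
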