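"""Landmark network: contracts, augmentation semantics, training behaviour."""

import numpy as np
import pytest

from orthoface import net
from orthoface import synthetic as syn
from orthoface.io import FaceImage, LandmarkSet
from orthoface.net import (
    DataError,
    TrainingConfig,
    augment,
    build_model,
    evaluate,
    load_model,
    predict,
    save_model,
    train,
)


def _rand_input(seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((3, 40, 40)).astype(np.float32)


class TestBuildModel:
    def test_shape_contract(self):
        m = build_model(TrainingConfig(seed=1))
        out = net._forward(m.params, _rand_input())
        assert out.shape == (13, 2)
        assert np.isfinite(out).all()
        assert ((out >= 0) & (out <= 1)).all()

    def test_seeded_builds_identical(self):
        m1 = build_model(TrainingConfig(seed=4))
        m2 = build_model(TrainingConfig(seed=4))
        x = _rand_input(1)
        np.testing.assert_array_equal(
            net._forward(m1.params, x), net._forward(m2.params, x)
        )

    def test_wrong_input_dimension_rejected(self):
        m = build_model(TrainingConfig(seed=0))
        with pytest.raises(ValueError):
            net._forward(m.params, np.zeros((3, 32, 32), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=2)
        with pytest.raises(ValueError):
            TrainingConfig.for_version(3)


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        pts = rng.uniform(5, 35, (13, 2))
        return FaceImage(px), LandmarkSet(pts, (40, 40))

    def test_flip_is_involution(self):
        img, lms = self._pair()
        rng = np.random.default_rng(0)
        i1, l1 = augment(img, lms, rng, force="flip")
        i2, l2 = augment(i1, l1, rng, force="flip")
        np.testing.assert_array_equal(i2.pixels, img.pixels)
        np.testing.assert_allclose(l2.points, lms.points)

    def test_flip_bilateral_swap_worked_example(self):
        # EyeRightInner (10,20) / EyeLeftInner (30,20) on width 40:
        # after the mirror, index 9 must hold (40-1-30, 20) = (9, 20)
        img, lms = self._pair()
        pts = lms.points.copy()
        pts[9] = (10, 20)
        pts[10] = (30, 20)
        lms = LandmarkSet(pts, (40, 40))
        _, flipped = augment(img, lms, np.random.default_rng(0), force="flip")
        np.testing.assert_allclose(flipped.points[9], (9, 20))
        np.testing.assert_allclose(flipped.points[10], (29, 20))

    def test_saturation_factor_one_is_identity(self):
        img, lms = self._pair()
        out, out_lms = augment(
            img, lms, np.random.default_rng(0),
            saturation_range=(1.0, 1.0), force="saturation",
        )
        assert np.abs(out.pixels.astype(int) - img.pixels.astype(int)).max() <= 1
        np.testing.assert_array_equal(out_lms.points, lms.points)

    def test_saturation_leaves_landmarks_unchanged(self):
        img, lms = self._pair()
        _, out_lms = augment(
            img, lms, np.random.default_rng(1),
            saturation_range=(0.6, 1.4), force="saturation",
        )
        np.testing.assert_array_equal(out_lms.points, lms.points)


class TestTraining:
    def test_loss_decreases_on_tiny_cohort(self, tiny_dataset):
        cfg = TrainingConfig(epochs=15, seed=2)
        model = build_model(cfg)
        _, hist = train(model, tiny_dataset["manifest_path"], cfg)
        assert len(hist.train_loss) == 15
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_training_is_deterministic(self, tiny_dataset):
        runs = []
        for _ in range(2):
            cfg = TrainingConfig(epochs=3, seed=6)
            model = build_model(cfg)
            _, hist = train(model, tiny_dataset["manifest_path"], cfg)
            runs.append(hist.train_loss)
        assert runs[0] == runs[1]

    def test_empty_split_rejected(self, tmp_path):
        manifest = {"_root": str(tmp_path), "annotations": "ann.json", "images": []}
        from orthoface.io import write_annotations

        write_annotations([], tmp_path / "ann.json")
        cfg = TrainingConfig(epochs=1, seed=0)
        with pytest.raises(DataError):
            train(build_model(cfg), manifest, cfg)

    def test_validation_history_recorded(self, tiny_dataset):
        cfg = TrainingConfig(epochs=3, seed=1)
        model = build_model(cfg)
        _, hist = train(model, tiny_dataset["manifest_path"], cfg, val_split="test")
        assert len(hist.val_loss) == 3

    def test_single_image_overfit(self, tmp_path):
        """1000 epochs on a 1-image dataset: the training image is recovered
        to within 2 px mean error at the 1024 frame."""
        cfg = syn.GeneratorConfig(n_subjects=1, seed=19, test_fraction=0.0)
        manifest_path = syn.generate_dataset(cfg, tmp_path)
        tcfg = TrainingConfig(epochs=1000, seed=19, augment=False)
        model = build_model(tcfg)
        model, hist = train(model, manifest_path, tcfg)
        man = syn.load_manifest(manifest_path)
        from orthoface.io import read_annotations, read_image

        rec = read_annotations(tmp_path / "annotations.json")[0]
        img = read_image(tmp_path / man["images"][0]["image"])
        pred = predict(model, img, rec.landmarks.frame)
        err = np.linalg.norm(pred.points - rec.landmarks.points, axis=1)
        assert err.mean() <= 2.0

    def test_loss_trend_first_vs_last_decile(self, tiny_dataset):
        cfg = TrainingConfig(epochs=30, seed=3)
        model = build_model(cfg)
        _, hist = train(model, tiny_dataset["manifest_path"], cfg)
        k = max(1, len(hist.train_loss) // 10)
        assert np.median(hist.train_loss[-k:]) < np.median(hist.train_loss[:k])


class TestPredictEvaluate:
    def test_rescale_arithmetic(self):
        m = build_model(TrainingConfig(seed=5))
        img = FaceImage(np.full((40, 40, 3), 128, dtype=np.uint8))
        out40 = net._forward(
            m.params, img.pixels.astype(np.float32).transpose(2, 0, 1) / np.float32(255)
        )
        pred = predict(m, img, (1024, 1024))
        np.testing.assert_allclose(pred.points, out40 * 1024, rtol=1e-6)

    def test_constant_input_finite(self):
        m = build_model(TrainingConfig(seed=6))
        img = FaceImage(np.full((1024, 1024, 3), 77, dtype=np.uint8))
        pred = predict(m, img)
        assert np.isfinite(pred.points).all()

    def test_perfect_predictions_zero_error(self, tiny_dataset, monkeypatch):
        from orthoface.io import read_annotations

        truth = {
            r.image_id: r.landmarks
            for r in read_annotations(tiny_dataset["dir"] / "annotations.json")
        }

        def fake_predict(model, image, crop_frame=None):
            return truth[image.id]

        monkeypatch.setattr(net, "predict", fake_predict)
        res = evaluate(object(), tiny_dataset["manifest_path"], "test")
        assert res["mean_normalized_error"] == 0.0

    def test_intercanthal_offset_normalizes_to_one(self, tiny_dataset, monkeypatch):
        from orthoface.io import read_annotations

        truth = {
            r.image_id: r.landmarks
            for r in read_annotations(tiny_dataset["dir"] / "annotations.json")
        }

        def fake_predict(model, image, crop_frame=None):
            lms = truth[image.id]
            icd = np.linalg.norm(lms.points[9] - lms.points[10])
            return LandmarkSet(lms.points + [icd, 0.0], lms.frame)

        monkeypatch.setattr(net, "predict", fake_predict)
        res = evaluate(object(), tiny_dataset["manifest_path"], "test")
        assert res["mean_normalized_error"] == pytest.approx(1.0, rel=1e-9)

    def test_empty_split_rejected(self, tiny_dataset):
        m = build_model(TrainingConfig(seed=0))
        with pytest.raises(DataError):
            evaluate(m, tiny_dataset["manifest_path"], "nonexistent")


class TestCheckpoint:
    def test_roundtrip_identical_predictions(self, tmp_path):
        m = build_model(TrainingConfig(seed=8))
        path = tmp_path / "model.npz"
        save_model(m, path)
        back = load_model(path)
        x = _rand_input(2)
        np.testing.assert_array_equal(
            net._forward(m.params, x), net._forward(back.params, x)
        )
        assert back.architecture == m.architecture

    def test_version_check(self, tmp_path):
        m = build_model(TrainingConfig(seed=8))
        path = tmp_path / "model.npz"
        save_model(m, path)
        data = dict(np.load(path, allow_pickle=False))
        data["__version__"] = np.array(99)
        np.savez(path, **data)
        with pytest.raises(ValueError):
            load_model(path)
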