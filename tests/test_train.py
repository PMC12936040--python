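"""Patient splitting, augmentation, standardization, loss, training loop."""

import numpy as np
import pytest

from alvedef.annotations import DefectClass, LandmarkPair, SliceAnnotation
from alvedef.nn import NetConfig, Tensor, cosine_lr
from alvedef.phantom import PhantomSpec, generate_dataset
from alvedef.train import (
    AugmentSpec,
    TrainConfig,
    augment,
    loss,
    split_patients,
    standardize,
    train_model,
)


class TestSplit:
    def test_20_patients_ratio(self):
        spec = split_patients([f"P{i}" for i in range(20)], (7, 2, 1), seed=0)
        sizes = {k: len(spec.patients(k)) for k in ("train", "val", "test")}
        assert sizes == {"train": 14, "val": 4, "test": 2}

    def test_10_patients_ratio(self):
        spec = split_patients([f"P{i}" for i in range(10)], (7, 2, 1), seed=1)
        sizes = {k: len(spec.patients(k)) for k in ("train", "val", "test")}
        assert sizes == {"train": 7, "val": 2, "test": 1}

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(17)]
        assert split_patients(ids, seed=5).assignment == split_patients(ids, seed=5).assignment

    def test_patient_disjoint_many_seeds(self):
        ids = [f"P{i}" for i in range(23)]
        for seed in range(200):
            spec = split_patients(ids, (7, 2, 1), seed=seed)
            subsets = [set(spec.patients(k)) for k in ("train", "val", "test")]
            assert subsets[0] | subsets[1] | subsets[2] == set(ids)
            assert not (subsets[0] & subsets[1] or subsets[0] & subsets[2] or subsets[1] & subsets[2])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_patients(["P0", "P1"], (7, 2, 1), seed=0)


class TestAugment:
    def _pair_annotation(self):
        return SliceAnnotation(
            "p", "t", 0, 0.25,
            [LandmarkPair(DefectClass.BUCCAL_DEHISCENCE, [30.0, 20.0], [40.0, 50.0])],
        )

    def test_identity_spec_is_noop(self, rng):
        img = rng.uniform(0, 255, (64, 64)).astype(np.float32)
        ann = self._pair_annotation()
        out, ann2 = augment(img, ann, AugmentSpec.identity(), rng)
        np.testing.assert_allclose(out, img)
        np.testing.assert_allclose(ann2.defects[0].p1, ann.defects[0].p1)

    def test_rotation_matches_affine_oracle(self):
        """Landmarks move by exactly the affine matrix applied to pixels:
        replicate the parameter draws with an identically seeded generator
        and apply the rotation independently."""
        spec = AugmentSpec(
            scale_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 90.0),
            translation_range_frac=(0.0, 0.0),
            blur_sigma_range_px=(0.0, 0.0),
            noise_sd_range=(0.0, 0.0),
        )
        img = np.random.default_rng(0).uniform(0, 255, (64, 64)).astype(np.float32)
        ann = self._pair_annotation()
        rng_aug = np.random.default_rng(77)
        rng_ref = np.random.default_rng(77)
        _ = rng_ref.uniform(1.0, 1.0)  # scale draw
        theta = np.deg2rad(rng_ref.uniform(0.0, 90.0))
        _, ann2 = augment(img, ann, spec, rng_aug)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        c = np.array([31.5, 31.5])
        if ann2.defects:  # pair may rotate out of bounds for large angles
            for before, after in ((ann.defects[0].p1, ann2.defects[0].p1),
                                  (ann.defects[0].p2, ann2.defects[0].p2)):
                expected = rot @ (before - c) + c
                assert np.hypot(*(after - expected)) < 0.5

    def test_photometric_only_keeps_landmarks(self, rng):
        spec = AugmentSpec(
            scale_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 0.0),
            translation_range_frac=(0.0, 0.0),
            blur_sigma_range_px=(1.0, 1.0),
            noise_sd_range=(0.03, 0.03),
        )
        img = rng.uniform(0, 255, (64, 64)).astype(np.float32)
        ann = self._pair_annotation()
        out, ann2 = augment(img, ann, spec, rng)
        assert not np.allclose(out, img)  # pixels changed
        np.testing.assert_array_equal(ann2.defects[0].p1, ann.defects[0].p1)
        np.testing.assert_array_equal(ann2.defects[0].p2, ann.defects[0].p2)

    def test_out_of_bounds_pairs_dropped(self, rng):
        spec = AugmentSpec(
            scale_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 0.0),
            translation_range_frac=(-0.9, 0.0),  # push far left/up
            blur_sigma_range_px=(0.0, 0.0),
            noise_sd_range=(0.0, 0.0),
        )
        img = np.zeros((64, 64), dtype=np.float32)
        ann = self._pair_annotation()
        found_drop = False
        for _ in range(20):
            _, ann2 = augment(img, ann, spec, rng)
            if len(ann2.defects) == 0:
                found_drop = True
                break
        assert found_drop


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        out = standardize(img)
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1.0) < 1e-5

    def test_affine_intensity_invariance(self, rng):
        img = rng.uniform(0, 255, (48, 48)).astype(np.float32)
        np.testing.assert_allclose(standardize(3.0 * img + 17.0), standardize(img), atol=1e-4)

    def test_constant_image_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(np.full((8, 8), 7.0))
        assert not out.any()


class TestLoss:
    def _target(self, shape=(1, 12, 16, 16)):
        return np.zeros(shape, dtype=np.float32)

    def test_perfect_prediction_near_zero(self):
        target = self._target()
        target[0, 0, 4:8, 4:8] = 1.0
        target[0, 1, 4:8, 4:8] = 0.6
        logits = np.where(target[:, [0, 3, 6, 9]] > 0, 20.0, -20.0).astype(np.float32)
        pred = target.copy()
        pred[:, [0, 3, 6, 9]] = logits
        assert float(loss(Tensor(pred), target).data) < 1e-6

    def test_constant_direction_offset_closed_form(self):
        target = self._target()
        pred = target.copy()
        cx, cy = 0.3, -0.4
        pred[:, [1, 4, 7, 10]] = cx
        pred[:, [2, 5, 8, 11]] = cy
        pred[:, [0, 3, 6, 9]] = -50.0  # saturate BCE to ~0
        # direction MSE is the mean over the 8 direction channels
        expected = (4 * cx**2 + 4 * cy**2) / 8
        assert float(loss(Tensor(pred), target).data) == pytest.approx(expected, rel=1e-4)

    def test_zero_logits_give_ln2_per_pixel(self):
        target = self._target()
        pred = target.copy()  # mask logits all zero
        val = float(loss(Tensor(pred), target).data)
        assert val == pytest.approx(np.log(2.0), rel=1e-5)

    def test_heatmap_mode_zero_on_zero(self):
        target = self._target()
        assert float(loss(Tensor(target.copy()), target, mode="heatmap").data) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(Tensor(np.zeros((1, 12, 8, 8), np.float32)), self._target())


class TestCosineSchedule:
    def test_monotone_tail(self):
        lrs = [cosine_lr(e, 30, 1e-3) for e in range(30)]
        assert lrs[-1] < lrs[0]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[-1] == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def tiny_training_setup():
    spec = PhantomSpec(image_height_px=64, image_width_px=48)
    dataset = generate_dataset(4, 2, spec, seed=13)
    slices = [p for s in dataset.series for p in s.slices]
    return slices


class TestTrainModel:
    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train_model([], NetConfig.tiny(), TrainConfig(epochs=1))

    def test_single_epoch_history(self, tiny_training_setup):
        cfg = TrainConfig(epochs=1, initial_lr=1e-3, batch_size=4, augment_spec=None)
        result = train_model(tiny_training_setup[:8], NetConfig.tiny(), cfg)
        assert len(result.history) == 1

    def test_overfit_loss_monotone_first_epochs(self, tiny_training_setup):
        """Memorization sanity check on a small fixed set."""
        cfg = TrainConfig(
            epochs=5, initial_lr=1e-3, batch_size=4, seed=0,
            bce_pos_weight=10.0, augment_spec=None,
        )
        result = train_model(tiny_training_setup[:20], NetConfig.tiny(), cfg)
        losses = result.history["train_loss"].to_numpy()
        assert np.all(np.diff(losses) < 0)

    def test_history_follows_cosine_schedule(self, tiny_training_setup):
        cfg = TrainConfig(epochs=3, initial_lr=2e-3, batch_size=4, augment_spec=None)
        result = train_model(tiny_training_setup[:8], NetConfig.tiny(), cfg)
        expected = [cosine_lr(e, 3, 2e-3) for e in range(3)]
        np.testing.assert_allclose(result.history["lr"], expected, rtol=1e-12)

    def test_heatmap_mode_trains(self, tiny_training_setup):
        cfg = TrainConfig(
            epochs=1, initial_lr=1e-3, batch_size=4,
            landmark_mode="heatmap", augment_spec=None,
        )
        result = train_model(tiny_training_setup[:8], NetConfig.tiny(), cfg)
        assert np.isfinite(result.history["train_loss"]).all()

    def test_reproducible_history(self, tiny_training_setup):
        cfg = TrainConfig(epochs=2, initial_lr=1e-3, batch_size=4, seed=3)
        r1 = train_model(tiny_training_setup[:8], NetConfig.tiny(seed=1), cfg)
        r2 = train_model(tiny_training_setup[:8], NetConfig.tiny(seed=1), cfg)
        np.testing.assert_array_equal(
            r1.history["train_loss"].to_numpy(), r2.history["train_loss"].to_numpy()
        )
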