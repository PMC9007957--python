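import math

import numpy as np
import pytest

import lwvessel as lw
from lwvessel.training_engine import plan_cycles

from conftest import small_params


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert lw.cosine_lr(0, 250) == pytest.approx(1e-2)
        assert lw.cosine_lr(250, 250) == pytest.approx(1e-8)
        assert lw.cosine_lr(125, 250) == pytest.approx((1e-2 + 1e-8) / 2)

    def test_monotone_non_increasing_within_cycle(self):
        trace = [lw.cosine_lr(s, 100) for s in range(101)]
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_invalid_cycle_rejected(self):
        with pytest.raises(ValueError):
            lw.cosine_lr(0, 0)


class TestWnetLoss:
    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([[[1.0], [0.0]], [[0.0], [1.0]]], np.float32)[None]
        eps = 1e-6
        p = np.clip(y, eps, 1 - eps)
        assert lw.wnet_loss(p, p, y).item() < 1e-4

    def test_half_constant_toy_oracle(self):
        # subnet 1 perfect, subnet 2 constant 0.5 on a 2x2 half-vessel target:
        # total loss = 0 + ln 2
        y = np.array([[[1.0], [1.0]], [[0.0], [0.0]]], np.float32)[None]
        perfect = np.clip(y, 1e-6, 1 - 1e-6)
        constant = np.full_like(y, 0.5)
        loss = lw.wnet_loss(perfect, constant, y).item()
        assert loss == pytest.approx(math.log(2), abs=1e-4)

    def test_symmetric_in_subnet_order(self):
        rng = np.random.default_rng(0)
        a = rng.random((1, 4, 4, 1)).astype(np.float32)
        b = rng.random((1, 4, 4, 1)).astype(np.float32)
        y = (rng.random((1, 4, 4, 1)) > 0.5).astype(np.float32)
        assert lw.wnet_loss(a, b, y).item() == pytest.approx(
            lw.wnet_loss(b, a, y).item(), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        a = np.zeros((1, 4, 4, 1), np.float32)
        with pytest.raises(ValueError):
            lw.wnet_loss(a, a, np.zeros((1, 2, 2, 1), np.float32))

    def test_loss_finite_on_extreme_probabilities(self):
        y = np.ones((1, 2, 2, 1), np.float32)
        p = np.zeros((1, 2, 2, 1), np.float32)  # maximally wrong
        val = lw.wnet_loss(p, p, y).item()
        assert np.isfinite(val) and val > 0


class TestAugmentation:
    def test_disabled_augmentation_is_identity(self, tiny_samples):
        s = tiny_samples[0]
        out = lw.augment(s, np.random.default_rng(0), lw.AugmentConfig.disabled())
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.label, s.label)
        np.testing.assert_array_equal(out.fov, s.fov)

    def test_flip_keeps_image_label_aligned(self, tiny_samples):
        s = tiny_samples[0]
        cfg = lw.AugmentConfig.flips_only()
        for seed in range(8):
            out = lw.augment(s, np.random.default_rng(seed), cfg)
            # whatever flip was drawn, it must be one of the 4 flip images
            candidates = [s.label, s.label[:, ::-1], s.label[::-1], s.label[::-1, ::-1]]
            assert any(np.array_equal(out.label, c) for c in candidates)
            imgs = [s.image, s.image[:, ::-1], s.image[::-1], s.image[::-1, ::-1]]
            i = next(j for j, c in enumerate(candidates) if np.array_equal(out.label, c))
            np.testing.assert_array_equal(out.image, imgs[i])

    def test_reproducible_given_seed(self, tiny_samples):
        s = tiny_samples[0]
        a = lw.augment(s, np.random.default_rng(5), lw.AugmentConfig())
        b = lw.augment(s, np.random.default_rng(5), lw.AugmentConfig())
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.label, b.label)

    def test_geometric_transform_keeps_masks_binary(self, tiny_samples):
        out = lw.augment(tiny_samples[1], np.random.default_rng(2),
                         lw.AugmentConfig())
        assert set(np.unique(out.label)) <= {0, 1}
        assert set(np.unique(out.fov)) <= {0, 1}


class TestTrainingLoop:
    def test_cycle_arithmetic(self):
        cfg = lw.TrainConfig(target_iterations=4000, cycle_epochs=50, batch_size=4)
        assert plan_cycles(20, cfg) == (5, 250, 16)
        cfg = lw.TrainConfig(target_iterations=250, cycle_epochs=50, batch_size=4)
        assert plan_cycles(20, cfg) == (5, 250, 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            lw.TrainConfig(lr_max=1e-8, lr_min=1e-2)
        with pytest.raises(ValueError):
            lw.TrainConfig(batch_size=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            lw.run_training([], [], spec=lw.ArchSpec(3, 8), cfg=lw.TrainConfig())

    def test_training_is_deterministic_given_seed(self):
        samples = lw.make_samples(4, seed=11, params=small_params(size=(32, 32)))
        cfg = lw.TrainConfig(target_iterations=4, cycle_epochs=2, batch_size=2,
                             seed=3, augment=lw.AugmentConfig.flips_only())
        runs = [lw.run_training(samples[:3], samples[3:],
                                spec=lw.ArchSpec(2, 4), cfg=cfg, kind="wnet")
                for _ in range(2)]
        assert runs[0].val_auc_history == runs[1].val_auc_history
        assert runs[0].loss_history == runs[1].loss_history

    def test_best_model_is_max_of_auc_history(self):
        samples = lw.make_samples(5, seed=12, params=small_params(size=(32, 32)))
        cfg = lw.TrainConfig(target_iterations=12, cycle_epochs=2, batch_size=2,
                             seed=0, augment=lw.AugmentConfig.disabled())
        bundle = lw.run_training(samples[:4], samples[4:],
                                 spec=lw.ArchSpec(2, 4), cfg=cfg, kind="wnet")
        assert bundle.best_val_auc == max(bundle.val_auc_history)
        assert bundle.best_cycle == bundle.val_auc_history.index(bundle.best_val_auc)
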