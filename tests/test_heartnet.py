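"""Tests of the heart-labelling network: masking contract, gradients,
augmentation pairing, and seeded determinism."""

import numpy as np
import pytest

from heartcac import heartnet
from heartcac.heartnet.model import (NetConfig, _pool_image, _stride_labels,
                                     masked_dice_loss, softmax, softmax_backward)
from heartcac.io_volumes import CTVolume, HeartMask
from heartcac.labelgen import UNLABELLED, SupervisionVolume

SPACING = (3.0, 0.7, 0.7)


class TestNormalize:
    def test_window_endpoints_and_midpoint(self):
        out = heartnet.normalize_input(np.array([[[-200.0, 650.0, 1500.0, 3000.0]]]),
                                       (-200.0, 1500.0))
        assert out[0, 0].tolist() == pytest.approx([0.0, 0.5, 1.0, 1.0])

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            heartnet.normalize_input(np.zeros((1, 1, 1)), (100.0, 100.0))


class TestConfig:
    def test_patch_must_divide_by_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(depth=3, patch_size=(12, 12, 12))

    def test_scalar_patch_broadcast(self):
        cfg = NetConfig(depth=2, patch_size=16)
        assert cfg.patch_size == (16, 16, 16)

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(epochs=0)


class TestNetwork:
    def test_same_seed_identical_initial_parameters(self):
        cfg = NetConfig(seed=9, patch_size=(8, 8, 8))
        a = heartnet.build_network(cfg)
        b = heartnet.build_network(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)
        c = heartnet.build_network(NetConfig(seed=10, patch_size=(8, 8, 8)))
        assert any(not np.array_equal(pa.value, pc.value)
                   for pa, pc in zip(a.params(), c.params()))

    def test_output_shape_and_probability_simplex(self):
        cfg = NetConfig(seed=0, patch_size=(8, 8, 8))
        net = heartnet.build_network(cfg)
        x = np.random.default_rng(0).normal(size=(2, 1, 8, 8, 8)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (6, 1, 8, 8, 8)
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop equals numerical gradients on a tiny net."""
        cfg = NetConfig(depth=2, base_channels=2, patch_size=(8, 8, 8),
                        seed=3, dtype="float64")
        net = heartnet.build_network(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 2, 8, 8, 8))
        labels = rng.integers(-1, 6, size=(2, 8, 8, 8)).astype(np.int16)
        probs = softmax(net.forward(x))
        _, gp = masked_dice_loss(probs, labels, return_grad=True)
        net.backward(softmax_backward(probs, gp))
        eps = 1e-6
        for p in net.params()[::5]:
            flat = p.value.ravel()
            for idx in rng.choice(flat.size, min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = masked_dice_loss(softmax(net.forward(x)), labels)
                flat[idx] = orig - eps
                lm = masked_dice_loss(softmax(net.forward(x)), labels)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num))


class TestMaskedDiceLoss:
    def _setup(self):
        rng = np.random.default_rng(1)
        labels = np.full((6, 10, 10), UNLABELLED, dtype=np.int16)
        labels[1, 2:5, 2:5] = 2
        labels[3, 6:9, 1:4] = 5
        labels[0] = 0
        probs_correct = np.full((6, 6, 10, 10), 1e-9)
        for c in range(6):
            probs_correct[c][labels == c] = 1.0
        # adversarial garbage at unsupervised voxels
        unsup = labels == UNLABELLED
        probs_correct[:, unsup] = 0.0
        probs_correct[5, unsup] = 1.0
        probs_correct /= probs_correct.sum(axis=0, keepdims=True)
        return labels, probs_correct, rng

    def test_correct_on_supervised_voxels_scores_near_zero(self):
        labels, probs, _ = self._setup()
        assert masked_dice_loss(probs, labels) <= 1e-3

    def test_complement_prediction_scores_near_one(self):
        labels, _, _ = self._setup()
        probs = np.full((6, 6, 10, 10), 0.0)
        wrong = (labels + 1) % 6
        for c in range(6):
            probs[c][wrong == c] = 1.0
        probs[0][labels == UNLABELLED] = 1.0
        assert masked_dice_loss(probs, labels) > 0.99

    def test_invariant_to_unsupervised_perturbation(self):
        labels, probs, rng = self._setup()
        base = masked_dice_loss(probs, labels)
        perturbed = probs.copy()
        unsup = labels == UNLABELLED
        noise = rng.dirichlet(np.ones(6), size=int(unsup.sum())).T
        perturbed[:, unsup] = noise
        assert masked_dice_loss(perturbed, labels) == base

    def test_gradient_zero_at_unsupervised_voxels(self):
        labels, probs, _ = self._setup()
        _, grad = masked_dice_loss(probs, labels, return_grad=True)
        assert np.all(grad[:, labels == UNLABELLED] == 0)
        assert np.any(grad[:, labels != UNLABELLED] != 0)

    def test_no_supervision_is_an_error(self):
        probs = np.full((6, 2, 2, 2), 1 / 6)
        labels = np.full((2, 2, 2), UNLABELLED, dtype=np.int16)
        with pytest.raises(ValueError, match="supervised"):
            masked_dice_loss(probs, labels)


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(2, 8, 16, 16)).astype(np.float32)
        labels = rng.integers(-1, 6, size=(8, 16, 16)).astype(np.int16)
        return img, labels

    def test_identity_parameters_return_input_unchanged(self):
        img, labels = self._pair()
        cfg = NetConfig(scale_range=(1.0, 1.0), noise_sigma_range=(0.0, 0.0),
                        max_shift=0, patch_size=(8, 16, 16))
        out_img, out_lab = heartnet.augment(img, labels, cfg, np.random.default_rng(1))
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lab, labels)

    def test_fixed_rng_reproducible(self):
        img, labels = self._pair()
        cfg = NetConfig(patch_size=(8, 16, 16))
        a = heartnet.augment(img, labels, cfg, np.random.default_rng(7))
        b = heartnet.augment(img, labels, cfg, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_image_and_labels_shift_together(self):
        cfg = NetConfig(scale_range=(1.0, 1.0), noise_sigma_range=(0.0, 0.0),
                        max_shift=3, patch_size=(8, 16, 16))
        img = np.zeros((1, 8, 16, 16), dtype=np.float32)
        labels = np.full((8, 16, 16), UNLABELLED, dtype=np.int16)
        img[0, 4, 8, 8] = 1.0
        labels[4, 8, 8] = 3
        out_img, out_lab = heartnet.augment(img, labels, cfg, np.random.default_rng(3))
        assert out_img.max() == pytest.approx(1.0)
        assert np.argwhere(out_lab == 3).tolist() == \
            np.argwhere(out_img[0] > 0.5).tolist()


class TestWorkingGrid:
    def test_pool_and_stride_shapes(self):
        x = np.zeros((2, 8, 12, 12), dtype=np.float32)
        lab = np.zeros((8, 12, 12), dtype=np.int16)
        assert _pool_image(x, (1, 4, 4)).shape == (2, 8, 3, 3)
        assert _stride_labels(lab, (1, 4, 4), UNLABELLED).shape == (8, 3, 3)

    def test_pool_averages_blocks(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        pooled = _pool_image(x, (1, 2, 2))
        assert pooled[0, 0, 0, 0] == pytest.approx(np.mean([0, 1, 4, 5]))


def tiny_dataset(n=2, shape=(12, 24, 24)):
    rng = np.random.default_rng(11)
    items = []
    for _ in range(n):
        hu = rng.normal(0, 20, size=shape).astype(np.float32)
        heart = np.zeros(shape, dtype=np.uint8)
        heart[2:10, 4:20, 4:20] = 1
        labels = np.full(shape, UNLABELLED, dtype=np.int16)
        labels[heart == 0] = 0
        labels[4:7, 8:12, 8:12] = 5
        labels[5, 14:18, 14:18] = 2
        hu[5, 14:18, 14:18] = 300.0
        items.append((CTVolume(hu, SPACING), HeartMask(heart, SPACING),
                      SupervisionVolume(labels, SPACING)))
    return items


def tiny_config(**kw):
    base = dict(depth=2, base_channels=4, patch_size=(8, 12, 12),
                working_downsample=(1, 2, 2), epochs=3, steps_per_epoch=4,
                batch_size=2, seed=5, learning_rate=1e-3)
    base.update(kw)
    return NetConfig(**base)


class TestTrainPredict:
    def test_training_reduces_loss_and_is_seeded(self):
        data = tiny_dataset()
        cfg = tiny_config(epochs=6)
        net1, log1 = heartnet.train(data, cfg)
        net2, log2 = heartnet.train(data, cfg)
        assert log1[0]["loss"] == log2[0]["loss"]
        assert log1[-1]["loss"] == log2[-1]["loss"]
        assert log1[-1]["loss"] < log1[0]["loss"]
        assert all(np.isfinite(row["loss"]) for row in log1)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            heartnet.train([], tiny_config())

    def test_predict_forces_outside_heart_to_zero(self):
        data = tiny_dataset(1)
        net, _ = heartnet.train(data, tiny_config(epochs=1))
        ct, heart, _ = data[0]
        labels, probs = heartnet.predict(ct, heart, net)
        assert labels.voxels.shape == ct.voxels.shape
        assert np.all(labels.voxels[heart.voxels == 0] == 0)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-6)

    def test_all_zero_mask_yields_all_zero_labels(self):
        data = tiny_dataset(1)
        net, _ = heartnet.train(data, tiny_config(epochs=1))
        ct = data[0][0]
        labels, _ = heartnet.predict(ct, np.zeros(ct.voxels.shape, dtype=np.uint8), net)
        assert not labels.voxels.any()

    def test_weights_round_trip(self, tmp_path):
        data = tiny_dataset(1)
        net, _ = heartnet.train(data, tiny_config(epochs=1))
        path = heartnet.save_weights(net, tmp_path / "w.npz")
        net2 = heartnet.load_weights(path)
        ct, heart, _ = data[0]
        a, _ = heartnet.predict(ct, heart, net)
        b, _ = heartnet.predict(ct, heart, net2)
        assert np.array_equal(a.voxels, b.voxels)
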