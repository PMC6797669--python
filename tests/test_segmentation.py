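"""Patch sampling, network correctness, tiled inference and Jaccard."""

import dataclasses

import numpy as np
import pytest

from usreg import Mask3D, UNetConfig, Volume3D, jaccard, predict_mask
from usreg.errors import GeometryError, SizeError
from usreg.segmentation import DatasetSplit, TrainedModel, sample_patches, train
from usreg.segmentation.layers import bce_with_logits, soft_dice_loss
from usreg.segmentation.unet import UNet3D

CFG = UNetConfig(patch_size=(12, 12, 12), padding=(4, 4, 4), batch_size=2,
                 base_channels=4, val_samples=4, val_interval=10,
                 max_iterations=20, seed=0)


class TestSamplePatches:
    def test_deterministic_origins(self, small_case):
        a = sample_patches(small_case, CFG, 15, rng=np.random.default_rng(5))
        b = sample_patches(small_case, CFG, 15, rng=np.random.default_rng(5))
        assert [p.origin for p in a] == [p.origin for p in b]

    def test_tile_shapes(self, small_case):
        for p in sample_patches(small_case, CFG, 6):
            assert p.input.shape == (20, 20, 20)
            assert p.label.shape == (12, 12, 12)

    def test_unbalanced_patch_in_empty_region_has_zero_label(self):
        vol = Volume3D(data=np.random.default_rng(0).random((32, 32, 32)),
                       spacing=(1, 1, 1), origin=(0, 0, 0))
        mask = Mask3D.like(vol, np.zeros((32, 32, 32), np.uint8))
        for p in sample_patches((vol, mask), CFG, 5, balanced=False):
            assert p.label.sum() == 0

    def test_nonpositive_count_rejected(self, small_case):
        with pytest.raises(ValueError):
            sample_patches(small_case, CFG, 0)


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        net = UNet3D(steps=2, base_channels=2, dropout=0.0, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 8, 8, 8))
        y = (rng.random((2, 1, 8, 8, 8)) > 0.7).astype(float)

        for p in net.params():
            p.grad[...] = 0
        logits = net.forward(x, training=True)
        _, dlog = bce_with_logits(logits, y)
        net.backward(dlog)

        eps = 1e-6
        params = net.params()
        for pi in (0, 5, len(params) - 1):
            p = params[pi]
            idx = tuple(rng.integers(s) for s in p.value.shape)
            old = p.value[idx]
            p.value[idx] = old + eps
            l2, _ = bce_with_logits(net.forward(x, training=True), y)
            p.value[idx] = old - eps
            l1, _ = bce_with_logits(net.forward(x, training=True), y)
            p.value[idx] = old
            num = (l2 - l1) / (2 * eps)
            assert abs(num - p.grad[idx]) < 1e-6 * max(1.0, abs(num))

    def test_loss_gradients_numerically(self, rng):
        z = rng.standard_normal((2, 1, 4, 4, 4))
        y = (rng.random(z.shape) > 0.5).astype(float)
        for fn in (bce_with_logits, soft_dice_loss):
            L, g = fn(z, y)
            eps = 1e-6
            i = (0, 0, 1, 2, 3)
            z2 = z.copy()
            z2[i] += eps
            L2, _ = fn(z2, y)
            assert abs((L2 - L) / eps - g[i]) < 1e-5

    def test_output_shape_with_odd_input(self):
        net = UNet3D(steps=2, base_channels=2, seed=0)
        x = np.random.default_rng(0).standard_normal((1, 1, 10, 11, 13)).astype(np.float32)
        assert net.forward(x).shape == (1, 1, 10, 11, 13)

    def test_probabilities_bounded(self):
        net = UNet3D(steps=2, base_channels=2, seed=0)
        x = np.random.default_rng(0).standard_normal((1, 1, 12, 12, 12)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.min() >= 0 and p.max() <= 1


class TestTraining:
    def test_history_bookkeeping_and_determinism(self, small_case):
        split = DatasetSplit(train=[small_case], validation=[dataclasses.replace(small_case)])
        m1 = train(split, CFG)
        m2 = train(split, CFG)
        assert len(m1.history) == CFG.max_iterations // CFG.val_interval
        assert m1.selected_checkpoint == m2.selected_checkpoint
        for k in m1.state:
            np.testing.assert_array_equal(m1.state[k], m2.state[k])
        # selected checkpoint maximizes the recorded validation Jaccard
        best = max(j for _, j in m1.history)
        sel = dict(m1.history)[m1.selected_checkpoint]
        assert sel == best

    def test_model_save_load_round_trip(self, small_case, tmp_path):
        split = DatasetSplit(train=[small_case], validation=[dataclasses.replace(small_case)])
        model = train(split, CFG)
        model.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        assert loaded.selected_checkpoint == model.selected_checkpoint
        b1, _ = predict_mask(model, small_case.volume)
        b2, _ = predict_mask(loaded, small_case.volume)
        np.testing.assert_array_equal(b1.data, b2.data)


class TestPredict:
    def test_output_geometry_matches_input(self, small_case):
        model = TrainedModel(config=CFG, state=UNet3D(steps=2, base_channels=4, seed=0).state_dict())
        binary, prob = predict_mask(model, small_case.volume)
        assert binary.shape == small_case.volume.shape
        assert prob.kind == "probability"
        assert float(prob.data.min()) >= 0 and float(prob.data.max()) <= 1

    def test_single_tile_volume_equals_whole_forward(self):
        rng = np.random.default_rng(3)
        vol = Volume3D(data=rng.random((12, 12, 12)).astype(np.float32),
                       spacing=(1, 1, 1), origin=(0, 0, 0))
        net = UNet3D(steps=2, base_channels=4, seed=0)
        model = TrainedModel(config=CFG, state=net.state_dict())
        _, prob = predict_mask(model, vol)
        data = (np.asarray(vol.data) - vol.data.mean()) / vol.data.std()
        padded = np.pad(data, 4, mode="reflect")
        direct = net.predict_proba(padded[None, None])[0, 0, 4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(np.asarray(prob.data), direct, atol=1e-6)

    def test_volume_smaller_than_core_rejected(self):
        vol = Volume3D(data=np.zeros((8, 8, 8), np.float32), spacing=(1, 1, 1), origin=(0, 0, 0))
        model = TrainedModel(config=CFG, state=UNet3D(steps=2, base_channels=4, seed=0).state_dict())
        with pytest.raises(SizeError):
            predict_mask(model, vol)

    def test_prediction_translation_equivariance(self):
        # rolling the content by one whole tile rolls the interior prediction
        rng = np.random.default_rng(8)
        data = rng.random((48, 12, 12)).astype(np.float32)
        v1 = Volume3D(data=data, spacing=(1, 1, 1), origin=(0, 0, 0))
        v2 = Volume3D(data=np.roll(data, 12, axis=0), spacing=(1, 1, 1), origin=(0, 0, 0))
        model = TrainedModel(config=CFG, state=UNet3D(steps=2, base_channels=4, seed=0).state_dict())
        _, p1 = predict_mask(model, v1)
        _, p2 = predict_mask(model, v2)
        np.testing.assert_allclose(
            np.asarray(p2.data)[24:36], np.asarray(p1.data)[12:24], atol=1e-5
        )


class TestJaccard:
    def _mask(self, arr):
        v = Volume3D(data=np.zeros(arr.shape, np.float32), spacing=(1, 1, 1), origin=(0, 0, 0))
        return Mask3D.like(v, arr.astype(np.uint8))

    def test_examples(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2, :2, :2] = True  # 8 voxels
        b = np.zeros((4, 4, 4), bool)
        b[1:3, :2, :2] = True  # 8 voxels, overlap 4
        assert jaccard(self._mask(a), self._mask(a)) == 1.0
        assert jaccard(self._mask(a), self._mask(np.roll(a, 2, axis=2))) == 0.0
        assert jaccard(self._mask(a), self._mask(b)) == pytest.approx(4 / 12)
        assert jaccard(self._mask(np.zeros((4, 4, 4), bool)), self._mask(np.zeros((4, 4, 4), bool))) == 1.0

    def test_geometry_mismatch(self):
        a = self._mask(np.zeros((4, 4, 4), bool))
        v = Volume3D(data=np.zeros((4, 4, 4), np.float32), spacing=(2, 2, 2), origin=(0, 0, 0))
        b = Mask3D.like(v, np.zeros((4, 4, 4), np.uint8))
        with pytest.raises(GeometryError):
            jaccard(a, b)
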