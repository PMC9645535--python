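"""Network arithmetic: gradients, gate limits, loss identities, training."""

import numpy as np
import pytest

from aortaseg.augment import TrainingCase
from aortaseg.core import LabelMask, Volume
from aortaseg.morphometry import dice_score
from aortaseg.nn import (
    AttentionGate,
    ModelConfig,
    build_model,
    one_hot,
    predict,
    probs_to_mask,
    soft_dice_loss,
    soft_dice_loss_grad,
    train,
)


class TestModelConfig:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=4, patch_size=12)

    @pytest.mark.parametrize("bad", [dict(depth=1), dict(out_classes=1)])
    def test_degenerate_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)


class TestForward:
    def test_probabilities_sum_to_one(self):
        m = build_model(ModelConfig(depth=3, base_channels=4, patch_size=32,
                                    seed=0))
        x = np.random.default_rng(0).normal(size=(1, 32, 32, 32)).astype(np.float32)
        p = m.forward(x)
        assert p.shape == (3, 32, 32, 32)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)

    def test_all_zero_input_finite(self):
        m = build_model(ModelConfig(depth=2, base_channels=4, patch_size=16))
        p = m.forward(np.zeros((1, 16, 16, 16), np.float32))
        assert np.isfinite(p).all()

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(1).normal(size=(1, 16, 16, 16)).astype(np.float32)
        pa = build_model(ModelConfig(depth=2, patch_size=16, seed=5)).forward(x)
        pb = build_model(ModelConfig(depth=2, patch_size=16, seed=5)).forward(x)
        np.testing.assert_array_equal(pa, pb)

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(depth=2, base_channels=2, patch_size=8, seed=1)
        m = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        t = rng.integers(0, 3, size=(8, 8, 8))
        _, g = soft_dice_loss_grad(m.forward(x), t)
        m.backward(g)
        checked = 0
        for lay in m._layers()[:3] + [m.head]:
            for p, gp in zip(lay.params(), lay.grads()):
                flat, gflat = p.ravel(), gp.ravel()
                for idx in (0, flat.size // 2):
                    eps, orig = 1e-3, flat[idx]
                    flat[idx] = orig + eps
                    lp, _ = soft_dice_loss_grad(m.forward(x), t, need_grad=False)
                    flat[idx] = orig - eps
                    lm, _ = soft_dice_loss_grad(m.forward(x), t, need_grad=False)
                    flat[idx] = orig
                    assert (lp - lm) / (2 * eps) == pytest.approx(
                        gflat[idx], abs=2e-3)
                    checked += 1
        assert checked >= 8


class TestAttentionGate:
    def _gate_and_inputs(self, per_channel=False):
        rng = np.random.default_rng(0)
        gate = AttentionGate(4, 8, rng, per_channel=per_channel)
        skip = rng.normal(size=(4, 8, 8, 8)).astype(np.float32)
        g = rng.normal(size=(8, 4, 4, 4)).astype(np.float32)
        return gate, skip, g

    def test_coefficients_in_unit_interval(self):
        gate, skip, g = self._gate_and_inputs()
        gate.forward(skip, g)
        assert gate.alpha.min() >= 0.0 and gate.alpha.max() <= 1.0

    def test_identity_limit(self):
        gate, skip, g = self._gate_and_inputs()
        gate.psi.w[...] = 0.0
        gate.psi.b[...] = 30.0  # sigmoid saturates to exactly 1.0 in float32
        out = gate.forward(skip, g)
        np.testing.assert_array_equal(out, skip)

    def test_zero_limit(self):
        gate, skip, g = self._gate_and_inputs()
        gate.psi.w[...] = 0.0
        gate.psi.b[...] = -100.0
        out = gate.forward(skip, g)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_irreconcilable_shapes_rejected(self):
        gate, skip, _ = self._gate_and_inputs()
        with pytest.raises(ValueError, match="half"):
            gate.forward(skip, np.zeros((8, 3, 3, 3), np.float32))

    def test_disabled_attention_equals_generic_unet(self):
        """Forcing every gate to alpha=1 reproduces the plain U-Net output
        of the same weights (the baseline architecture)."""
        cfg = ModelConfig(depth=3, base_channels=4, patch_size=16, seed=2)
        m = build_model(cfg)
        x = np.random.default_rng(3).normal(size=(1, 16, 16, 16)).astype(np.float32)
        for g in m.gates:
            g.psi.w[...] = 0.0
            g.psi.b[...] = 30.0
        p_gated = m.forward(x)
        gates, m.gates = m.gates, [None] * len(m.gates)
        p_plain = m.forward(x)
        m.gates = gates
        np.testing.assert_array_equal(p_gated, p_plain)


class TestSoftDiceLoss:
    def test_perfect_one_hot_prediction_scores_zero(self):
        t = np.random.default_rng(0).integers(0, 3, size=(6, 6, 6))
        assert soft_dice_loss(one_hot(t, 3), t) == pytest.approx(0.0, abs=1e-4)

    def test_uniform_prediction_matches_hand_formula(self):
        # 2x2x2 grid, 5 voxels class 1, 3 voxels class 2, uniform probs 1/3
        t = np.array([1, 1, 1, 1, 1, 2, 2, 2]).reshape(2, 2, 2)
        p = np.full((3, 2, 2, 2), 1 / 3, np.float32)
        eps = 1e-5
        d1 = (2 * (5 / 3) + eps) / (8 / 3 + 5 + eps)
        d2 = (2 * (3 / 3) + eps) / (8 / 3 + 3 + eps)
        expected = 1 - (d1 + d2) / 2
        assert soft_dice_loss(p, t) == pytest.approx(expected, abs=1e-6)

    def test_disjoint_hard_prediction_scores_one(self):
        t = np.zeros((4, 4, 4), int)
        t[:2] = 1
        pred = np.zeros((4, 4, 4), int)
        pred[2:] = 1  # disjoint
        loss = soft_dice_loss(one_hot(pred, 2), t)
        assert loss == pytest.approx(1.0, abs=1e-4)

    def test_empty_class_convention(self):
        t = np.zeros((4, 4, 4), int)  # class 1 absent everywhere
        assert soft_dice_loss(one_hot(t, 2), t) == pytest.approx(0.0)

    def test_agrees_with_hard_dice_score(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(0, 3, size=(6, 6, 6)).astype(np.uint8)
            b = rng.integers(0, 3, size=(6, 6, 6)).astype(np.uint8)
            loss = soft_dice_loss(one_hot(a, 3), b)
            hard = np.mean([dice_score(LabelMask(a, (1, 1, 1)),
                                       LabelMask(b, (1, 1, 1)), c)
                            for c in (1, 2)])
            assert loss == pytest.approx(1 - hard, abs=1e-3)


class TestTrainPredict:
    def _cases(self, n=4, size=16):
        rng = np.random.default_rng(0)
        cases = []
        for i in range(n):
            lab = np.zeros((size,) * 3, np.uint8)
            c = size // 2 + rng.integers(-2, 3)
            lab[c - 3:c + 3, c - 3:c + 3, 2:size - 2] = 1
            img = lab * 0.8 + rng.normal(0, 0.05, lab.shape)
            cases.append(TrainingCase(
                Volume(img.astype(np.float32), (1, 1, 1)),
                LabelMask(lab, (1, 1, 1)), f"t{i}"))
        return cases

    def test_loss_trend_decreases(self):
        cases = self._cases()
        model = build_model(ModelConfig(depth=2, base_channels=4,
                                        out_classes=2, patch_size=16, seed=0))
        hist = train(model, cases, epochs=12, online_augment=False, seed=1,
                     early_stop_loss=None)
        df = hist.to_frame()
        assert df["train_loss"].iloc[-5:].mean() < df["train_loss"].iloc[:5].mean()

    def test_no_foreground_raises_data_error(self):
        img = Volume(np.zeros((16, 16, 16), np.float32), (1, 1, 1))
        msk = LabelMask(np.zeros((16, 16, 16), np.uint8), (1, 1, 1))
        cases = [TrainingCase(img, msk, "a"), TrainingCase(img, msk, "b")]
        model = build_model(ModelConfig(depth=2, out_classes=2, patch_size=16))
        with pytest.raises(ValueError, match="foreground"):
            train(model, cases, epochs=1)

    def test_predict_is_deterministic_and_normalized(self):
        model = build_model(ModelConfig(depth=2, base_channels=4,
                                        out_classes=2, patch_size=16, seed=4))
        v = Volume(np.random.default_rng(5).normal(
            size=(20, 20, 20)).astype(np.float32), (1, 1, 1))
        p1, p2 = predict(model, v), predict(model, v)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=0), 1.0, atol=1e-5)

    def test_predict_pads_small_volumes(self):
        model = build_model(ModelConfig(depth=2, base_channels=4,
                                        out_classes=2, patch_size=16, seed=4))
        v = Volume(np.zeros((10, 10, 10), np.float32), (1, 1, 1))
        assert predict(model, v).shape == (2, 10, 10, 10)

    def test_checkpoint_roundtrip(self, tmp_path):
        from aortaseg.nn.unet import AttentionUNet3D

        model = build_model(ModelConfig(depth=2, base_channels=4,
                                        patch_size=16, seed=9))
        x = np.random.default_rng(6).normal(size=(1, 16, 16, 16)).astype(np.float32)
        before = model.forward(x)
        path = model.save(tmp_path / "m.npz")
        after = AttentionUNet3D.load(path).forward(x)
        np.testing.assert_array_equal(before, after)
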