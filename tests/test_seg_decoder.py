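"""Segmentation decoder: shape/softmax contracts, modulation identity,
Dice and combined losses."""

import numpy as np
import pytest

from glocalmm.encoders import EncoderSpec, VisualEncoder
from glocalmm.nn import Tensor
from glocalmm.seg_decoder import (DecoderConfig, SegmentationModel,
                                  TextModulation, cross_entropy_loss,
                                  decode_segmentation, dice_loss, one_hot,
                                  segmentation_loss)


@pytest.fixture(scope="module")
def seg_model():
    spec = EncoderSpec.tiny()
    enc = VisualEncoder(spec, np.random.default_rng(0))
    return SegmentationModel(enc, DecoderConfig(), text_dim=spec.shared_dim,
                             seed=1)


class TestDecoder:
    def test_output_shape_and_softmax_invariant(self, seg_model):
        img = np.random.default_rng(1).random((64, 64))
        pred = decode_segmentation(seg_model, img)
        assert pred.probs.shape == (64, 64, 4)
        assert (pred.probs >= 0).all()
        np.testing.assert_allclose(pred.probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.array_equal(pred.argmax_mask, pred.probs.argmax(axis=-1))

    def test_determinism(self, seg_model):
        img = np.random.default_rng(2).random((64, 64))
        p1 = decode_segmentation(seg_model, img)
        p2 = decode_segmentation(seg_model, img)
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_modulation_off_is_identity_path(self):
        spec = EncoderSpec.tiny()
        enc = VisualEncoder(spec, np.random.default_rng(3))
        cfg_on = DecoderConfig(text_modulation=True)
        cfg_off = DecoderConfig(text_modulation=False)
        m_on = SegmentationModel(enc, cfg_on, text_dim=spec.shared_dim, seed=5)
        m_off = SegmentationModel(enc, cfg_off, text_dim=spec.shared_dim, seed=5)
        img = Tensor(np.random.default_rng(4).random((1, 1, 64, 64)))
        # passing no text through an enabled modulator is also the identity
        np.testing.assert_array_equal(m_on(img, None).data, m_off(img, None).data)

    def test_stage_mismatch_raises(self):
        spec = EncoderSpec.tiny()
        enc = VisualEncoder(spec, np.random.default_rng(0))
        with pytest.raises(ValueError):
            SegmentationModel(enc, DecoderConfig(n_stages=5), text_dim=8)


class TestTextModulation:
    def test_no_text_identity(self):
        mod = TextModulation(8, 16, 4, np.random.default_rng(0))
        fmap = Tensor(np.random.default_rng(1).random((2, 8, 4, 4)))
        np.testing.assert_array_equal(mod(fmap, None).data, fmap.data)
        empty = Tensor(np.zeros((2, 0, 16)))
        np.testing.assert_array_equal(mod(fmap, empty).data, fmap.data)

    def test_uniform_attention_adds_constant_residual(self):
        rng = np.random.default_rng(2)
        mod = TextModulation(8, 16, 4, rng)
        # constant spatial features -> equal attention logits everywhere
        fmap = Tensor(np.ones((1, 8, 4, 4)) * 0.3)
        t_l = Tensor(rng.random((1, 2, 16)))
        out = mod(fmap, t_l).data
        residual = out - fmap.data
        # the same vector is added at every spatial position
        np.testing.assert_allclose(
            residual, np.broadcast_to(residual[:, :, :1, :1], residual.shape),
            atol=1e-12)

    def test_single_word_residual_matches_hand_attention_trace(self):
        rng = np.random.default_rng(3)
        mod = TextModulation(4, 6, 3, rng)
        fmap_data = rng.random((1, 4, 2, 2))
        q = rng.random(3)
        t_l = rng.random((1, 1, 6))
        mod.wq.weight.data[...] = 0.0      # query = bias, independent of text
        mod.wq.bias.data[...] = q
        out = mod(Tensor(fmap_data), Tensor(t_l)).data
        # hand trace: softmax over the 4 positions, value-weighted summary
        flat = fmap_data.reshape(1, 4, 4).swapaxes(1, 2)     # (1, hw, C)
        keys = mod.wk(Tensor(flat)).data[0]
        vals = mod.wv(Tensor(flat)).data[0]
        logits = keys @ q / np.sqrt(3)
        e = np.exp(logits - logits.max())
        attended = (e / e.sum()) @ vals
        expect = mod.wo(Tensor(attended)).data
        np.testing.assert_allclose(
            out - fmap_data,
            np.broadcast_to(expect.reshape(1, -1, 1, 1), fmap_data.shape),
            atol=1e-9)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        target = one_hot(np.array([[0, 1], [1, 0]]), 2)
        assert dice_loss(target, target, smoothing=1.0) < 0.2
        assert dice_loss(target, target, smoothing=1e-9) == pytest.approx(0.0,
                                                                          abs=1e-6)

    def test_disjoint_prediction_is_one(self):
        pred = one_hot(np.array([[0, 0], [0, 0]]), 2)
        target = one_hot(np.array([[1, 1], [1, 1]]), 2)
        assert dice_loss(pred, target, smoothing=1e-12) == pytest.approx(1.0)

    def test_uniform_half_foreground_hand_value(self):
        # uniform 0.5 probabilities, K=2, target half foreground:
        # per-class soft Dice = (2*0.5*n/2)/(0.5*n + n/2) = 0.5
        n = 16
        probs = np.full((2, 4, 4), 0.5)
        target = np.zeros((4, 4), dtype=int)
        target[:2] = 1
        loss = dice_loss(probs, one_hot(target, 2), smoothing=1e-12)
        assert loss == pytest.approx(0.5, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 4, 4)), np.zeros((3, 4, 4)))

    def test_bounded_and_monotone_in_overlap(self):
        # nested predictions: more overlap -> smaller loss
        target = np.zeros((8, 8), dtype=int)
        target[2:6, 2:6] = 1
        goh = one_hot(target, 2)
        losses = []
        for grow in range(4):
            pred = np.zeros((8, 8), dtype=int)
            pred[2:2 + grow + 1, 2:6] = 1
            losses.append(dice_loss(one_hot(pred, 2), goh, smoothing=1e-12))
        assert all(0 <= v <= 1 for v in losses)
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestSegmentationLoss:
    def test_perfect_prediction_near_zero(self):
        cfg = DecoderConfig(dice_smoothing=1e-9)
        target = one_hot(np.array([[0, 1], [2, 3]]), 4)
        probs = np.clip(target, 1e-9, 1.0)
        probs /= probs.sum(axis=0, keepdims=True)
        assert segmentation_loss(probs, target, cfg) == pytest.approx(0.0, abs=1e-4)

    def test_aux_isolation(self):
        rng = np.random.default_rng(0)
        logits = rng.random((4, 4, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        target = one_hot(rng.integers(0, 4, size=(4, 4)), 4)
        off = segmentation_loss(probs, target, DecoderConfig(aux_alignment=False),
                                aux_loss=123.0)
        on_zero = segmentation_loss(probs, target, DecoderConfig(aux_alignment=True),
                                    aux_loss=0.0)
        assert off == pytest.approx(on_zero)

    def test_recomposition_matches_parts(self):
        rng = np.random.default_rng(1)
        logits = rng.random((3, 5, 5))
        probs = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        target = one_hot(rng.integers(0, 3, size=(5, 5)), 3)
        cfg = DecoderConfig(k_classes=3, aux_alignment=True, aux_weight=0.25)
        total = segmentation_loss(probs, target, cfg, aux_loss=0.8)
        expect = (dice_loss(probs, target, cfg.dice_smoothing)
                  + cross_entropy_loss(probs, target) + 0.25 * 0.8)
        assert total == pytest.approx(expect, abs=1e-9)

    def test_gradient_flows_through_tensor_path(self):
        rng = np.random.default_rng(2)
        logits = Tensor(rng.random((1, 3, 4, 4)), requires_grad=True)
        from glocalmm.nn import functional as F
        probs = F.softmax(logits, axis=1)
        target = one_hot(rng.integers(0, 3, size=(1, 4, 4)), 3)
        loss = segmentation_loss(probs, target, DecoderConfig(k_classes=3))
        loss.backward()
        assert logits.grad is not None and np.isfinite(logits.grad).all()
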