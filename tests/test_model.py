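"""Architecture contracts: patch embedding, sequence reduction, attention,
mix-FFN, encoder pyramid, decoder logits, prediction."""

import math

import numpy as np
import pytest

from larynxseg.model import (
    EfficientSelfAttention,
    FeaturePyramid,
    MixFFN,
    ModelConfig,
    OverlapPatchEmbed,
    SegmentationModel,
    SequenceReduction,
    TokenGrid,
    load_checkpoint,
    predict,
    reduce_sequence,
    save_checkpoint,
    tokens_to_grid,
)
from larynxseg.nn import Tensor, no_grad


def _rng():
    return np.random.default_rng(0)


class TestOverlapPatchEmbed:
    def test_stage1_gives_quarter_resolution_tokens(self):
        embed = OverlapPatchEmbed(_rng(), 3, 16, kernel=7, stride=4)
        out = embed(Tensor(np.random.default_rng(1).random((1, 3, 128, 128))))
        assert out.grid_shape == (32, 32)
        assert out.tokens.shape == (1, 1024, 16)

    def test_stride2_halves_feature_grid(self):
        embed = OverlapPatchEmbed(_rng(), 16, 32, kernel=3, stride=2)
        out = embed(Tensor(np.zeros((2, 16, 32, 32))))
        assert out.grid_shape == (16, 16)

    def test_zero_input_gives_zero_projection(self):
        embed = OverlapPatchEmbed(_rng(), 3, 8, kernel=7, stride=4)
        projected = embed.proj(Tensor(np.zeros((1, 3, 32, 32))))
        assert np.allclose(projected.data, 0.0)

    def test_translation_by_one_stride_shifts_tokens(self):
        embed = OverlapPatchEmbed(_rng(), 1, 4, kernel=7, stride=4)
        x = np.random.default_rng(2).random((1, 1, 64, 64)).astype(np.float32)
        shifted = np.roll(x, 4, axis=3)
        a = embed.proj(Tensor(x)).data.reshape(4, 16, 16)
        b = embed.proj(Tensor(shifted)).data.reshape(4, 16, 16)
        # interior columns shift by exactly one token
        np.testing.assert_allclose(b[:, :, 2:-1], a[:, :, 1:-2], atol=1e-5)


class TestSequenceReduction:
    def test_shape_arithmetic_n64_c8_r4(self):
        red = SequenceReduction(_rng(), dim=8, ratio=4)
        x = Tensor(np.random.default_rng(1).random((1, 64, 8)))
        # intermediate reshape is (N/R) x (C*R) = 16 x 32
        assert x.data.reshape(1, 16, 32).shape == (1, 16, 32)
        assert red(x).shape == (1, 16, 8)

    def test_shape_arithmetic_n1024_c32_r8(self):
        red = SequenceReduction(_rng(), dim=32, ratio=8)
        out = red(Tensor(np.random.default_rng(1).random((2, 1024, 32))))
        assert out.shape == (2, 128, 32)

    def test_ratio_one_is_identity(self):
        red = SequenceReduction(_rng(), dim=8, ratio=1)
        x = Tensor(np.random.default_rng(1).random((1, 64, 8)))
        assert np.array_equal(red(x).data, x.data)

    def test_indivisible_length_is_padded(self):
        # N not divisible by R is zero-padded to length ceil(N/R)*R first
        from larynxseg.nn import Linear
        lin = Linear(_rng(), 24, 8)
        out = reduce_sequence(Tensor(np.zeros((1, 15, 8))), 3, lin)
        assert out.shape == (1, 5, 8)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            SequenceReduction(_rng(), dim=8, ratio=0)


def brute_force_mha(x, attn: EfficientSelfAttention):
    """Independent multi-head softmax(QK^T/sqrt(d))V reference (R=1)."""
    B, N, C = x.shape
    h = attn.heads
    d = C // h
    q = x @ attn.q_proj.weight.data + attn.q_proj.bias.data
    k = x @ attn.k_proj.weight.data + attn.k_proj.bias.data
    v = x @ attn.v_proj.weight.data + attn.v_proj.bias.data
    out = np.empty_like(q)
    for b in range(B):
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            scores = q[b, :, sl] @ k[b, :, sl].T / math.sqrt(d)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            w = e / e.sum(axis=1, keepdims=True)
            out[b, :, sl] = w @ v[b, :, sl]
    return out @ attn.out_proj.weight.data + attn.out_proj.bias.data


class TestEfficientSelfAttention:
    def test_attention_rows_are_probability_distributions(self):
        attn = EfficientSelfAttention(_rng(), dim=16, heads=4, ratio=4)
        x = Tensor(np.random.default_rng(3).random((2, 64, 16)))
        _, weights = attn(x, return_weights=True)
        sums = weights.data.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    @pytest.mark.parametrize("heads,n,c", [(1, 8, 4), (2, 16, 8), (4, 12, 8)])
    def test_r1_matches_brute_force_reference(self, heads, n, c):
        attn = EfficientSelfAttention(_rng(), dim=c, heads=heads, ratio=1)
        x = np.random.default_rng(4).random((2, n, c)).astype(np.float32)
        with no_grad():
            out = attn(Tensor(x)).data
        np.testing.assert_allclose(out, brute_force_mha(x, attn), atol=1e-5)

    def test_constant_tokens_give_constant_output(self):
        attn = EfficientSelfAttention(_rng(), dim=8, heads=2, ratio=1)
        x = Tensor(np.ones((1, 10, 8), dtype=np.float32) * 0.3)
        out = attn(x).data
        np.testing.assert_allclose(out, np.broadcast_to(out[:, :1, :], out.shape),
                                   atol=1e-6)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            EfficientSelfAttention(_rng(), dim=10, heads=4, ratio=1)


class TestMixFFN:
    def _zeroed(self, dim=4, expansion=2):
        ffn = MixFFN(_rng(), dim, expansion)
        for p in ffn.parameters():
            p.data[:] = 0
        return ffn

    def test_zero_weights_make_residual_identity(self):
        ffn = self._zeroed()
        x = np.random.default_rng(5).random((2, 16, 4)).astype(np.float32)
        out = ffn(TokenGrid(tokens=Tensor(x), grid_shape=(4, 4)))
        np.testing.assert_allclose(out.tokens.data, x, atol=0)

    def test_output_shape_matches_input(self):
        ffn = MixFFN(_rng(), 8, 4)
        x = Tensor(np.random.default_rng(6).random((3, 64, 8)))
        out = ffn(TokenGrid(tokens=x, grid_shape=(8, 8)))
        assert out.tokens.shape == (3, 64, 8)

    def test_single_token_scalar_oracle(self):
        # dim 1, expansion 1; identity linears, pass-through (centre-tap) conv:
        # out = MLP(GELU(MLP(x))) + x = gelu(x) + x, hand-computable
        ffn = MixFFN(_rng(), dim=1, expansion=1)
        ffn.fc1.weight.data = np.array([[1.0]], dtype=np.float32)
        ffn.fc1.bias.data[:] = 0
        ffn.fc2.weight.data = np.array([[1.0]], dtype=np.float32)
        ffn.fc2.bias.data[:] = 0
        ffn.conv.weight.data[:] = 0
        ffn.conv.weight.data[0, 1, 1] = 1.0   # identity convolution
        ffn.conv.bias.data[:] = 0
        v = 0.7
        out = ffn(TokenGrid(tokens=Tensor([[[v]]]), grid_shape=(1, 1)))
        expected = v * 0.5 * (1 + math.erf(v / math.sqrt(2))) + v
        assert out.tokens.data[0, 0, 0] == pytest.approx(expected, abs=1e-6)


class TestEncoderDecoder:
    def test_pyramid_ratios_128(self, micro_model):
        x = Tensor(np.random.default_rng(7).random((1, 3, 128, 128)))
        with no_grad():
            pyr = micro_model.encoder(x)
        sizes = [lv.shape[2:] for lv in pyr.levels]
        assert sizes == [(32, 32), (16, 16), (8, 8), (4, 4)]
        dims = [lv.shape[1] for lv in pyr.levels]
        assert dims == list(micro_model.config.embed_dims)

    def test_pyramid_ratios_64(self, micro_model):
        x = Tensor(np.random.default_rng(7).random((1, 3, 64, 64)))
        with no_grad():
            pyr = micro_model.encoder(x)
        assert [lv.shape[2:] for lv in pyr.levels] == [(16, 16), (8, 8), (4, 4), (2, 2)]

    def test_pyramid_always_four_levels(self):
        with pytest.raises(ValueError):
            FeaturePyramid(levels=[Tensor(np.zeros((1, 4, 8, 8)))] * 3)

    def test_too_small_input_rejected(self, micro_model):
        with pytest.raises(ValueError):
            micro_model(np.zeros((1, 3, 16, 16), dtype=np.float32))

    def test_logits_full_resolution_three_channels(self, micro_model):
        with no_grad():
            logits = micro_model(np.random.default_rng(8).random((1, 3, 64, 64)).astype(np.float32))
        assert logits.shape == (1, 3, 64, 64)

    def test_zero_pyramid_gives_spatially_constant_logits(self, micro_model):
        levels = [Tensor(np.zeros((1, c, s, s), dtype=np.float32))
                  for c, s in zip(micro_model.config.embed_dims, (16, 8, 4, 2))]
        with no_grad():
            logits = micro_model.decoder(FeaturePyramid(levels=levels), (64, 64)).data
        np.testing.assert_allclose(
            logits, np.broadcast_to(logits[:, :, :1, :1], logits.shape), atol=1e-6)

    def test_doubling_input_doubles_logits(self, micro_model):
        with no_grad():
            a = micro_model(np.zeros((1, 3, 32, 32), dtype=np.float32))
            b = micro_model(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert a.shape[2:] == (32, 32) and b.shape[2:] == (64, 64)

    def test_non_multiple_of_32_input_is_padded_and_cropped(self, micro_model):
        with no_grad():
            logits = micro_model(np.zeros((1, 3, 100, 72), dtype=np.float32))
        assert logits.shape == (1, 3, 100, 72)

    def test_default_config_is_segformer_shaped(self):
        cfg = ModelConfig()
        assert cfg.patch_strides == (4, 2, 2, 2)
        assert int(np.prod(cfg.patch_strides)) == 32
        with pytest.raises(ValueError):
            ModelConfig(patch_strides=(2, 2, 2, 2))


class TestPredict:
    def test_argmax_semantics_and_tie_break(self, micro_model):
        logits = np.zeros((1, 3, 4, 4), dtype=np.float32)
        logits[0, 0] = 1.0                      # background everywhere
        mask_bg = np.argmax(logits, axis=1)
        assert (mask_bg == 0).all()
        logits[0, 1, 1:3, 1:3] = 2.0            # class 1 rectangle
        assert (np.argmax(logits, axis=1)[0, 1:3, 1:3] == 1).all()
        tie = np.zeros((1, 3, 1, 1), dtype=np.float32)
        tie[0, 1] = tie[0, 2] = 5.0             # two-way tie between 1 and 2
        assert np.argmax(tie, axis=1)[0, 0, 0] == 1

    def test_predict_returns_uint8_labels(self, micro_model, small_dataset):
        masks = predict([s.image for s in small_dataset[:2]], micro_model)
        assert masks.shape == (2, 64, 64)
        assert masks.dtype == np.uint8
        assert set(np.unique(masks)) <= {0, 1, 2}


def test_checkpoint_roundtrip(tmp_path, micro_model, small_dataset):
    path = tmp_path / "model.npz"
    save_checkpoint(micro_model, path)
    restored = load_checkpoint(path)
    assert restored.config == micro_model.config
    a = predict([small_dataset[0].image], micro_model)
    b = predict([small_dataset[0].image], restored)
    assert np.array_equal(a, b)
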