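"""Encoder correctness: positional encoding values, attention against a
brute-force per-position oracle, shape/determinism contracts, head
independence and gradient flow."""

import numpy as np
import pytest

from maft.autodiff import Tensor
from maft.transformer import (
    AttentionWeights,
    DepressionTransformer,
    EncoderConfig,
    NumericError,
    attention_matrix,
    positional_encoding,
    self_attention,
    temporal_average,
)


def _toy_model(input_dim=4, **cfg_overrides) -> DepressionTransformer:
    cfg = dict(num_layers=1, num_heads=1, ff_hidden=8, embed_dim=6, dropout=0.1)
    cfg.update(cfg_overrides)
    return DepressionTransformer(input_dim, EncoderConfig(**cfg), seed=3)


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 6)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)  # sin(0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)  # cos(0)

    def test_position_one_first_column_is_sin_one(self):
        pe = positional_encoding(3, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))
        assert pe[1, 2] == pytest.approx(np.sin(1.0 / 10000.0 ** (2.0 / 4.0)))

    def test_odd_d_model_final_column_is_sine(self):
        pe = positional_encoding(5, 5)
        expected = np.sin(np.arange(5) / 10000.0 ** (4.0 / 5.0))
        np.testing.assert_allclose(pe[:, 4], expected)


def _brute_force_attention(x: np.ndarray, w: AttentionWeights) -> np.ndarray:
    """Per-position scalar evaluation: similarity, softmax row-normalization,
    weighted sum of values, then the output projection."""
    q = x @ w.wq.w.data + w.wq.b.data
    k = x @ w.wk.w.data + w.wk.b.data
    v = x @ w.wv.w.data + w.wv.b.data
    t, d_k = q.shape
    z = np.zeros_like(v)
    for j in range(t):
        scores = np.array([q[j] @ k[i] / np.sqrt(d_k) for i in range(t)])
        alpha = np.exp(scores) / np.exp(scores).sum()
        for i in range(t):
            z[j] += alpha[i] * v[i]
    return z @ w.wo.w.data + w.wo.b.data


class TestSelfAttention:
    def test_single_frame_attends_only_to_itself(self):
        rng = np.random.default_rng(0)
        w = AttentionWeights.create(rng, 4, 1)
        x = Tensor(rng.standard_normal((1, 1, 4)))
        attn = attention_matrix(x, w)
        np.testing.assert_allclose(attn, 1.0)
        v = x.data[0] @ w.wv.w.data + w.wv.b.data
        expected = v @ w.wo.w.data + w.wo.b.data
        np.testing.assert_allclose(self_attention(x, w).data[0], expected)

    def test_identical_keys_give_uniform_attention_and_mean_value(self):
        rng = np.random.default_rng(1)
        w = AttentionWeights.create(rng, 4, 1)
        w.wk.w.data[:] = 0.0  # all keys collapse to the bias -> uniform rows
        x = Tensor(rng.standard_normal((1, 6, 4)))
        attn = attention_matrix(x, w)
        np.testing.assert_allclose(attn, 1.0 / 6.0)
        v = x.data[0] @ w.wv.w.data + w.wv.b.data
        expected = v.mean(axis=0) @ w.wo.w.data + w.wo.b.data
        out = self_attention(x, w).data[0]
        np.testing.assert_allclose(out, np.tile(expected, (6, 1)), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        w = AttentionWeights.create(rng, 4, 1)
        x = rng.standard_normal((3, 4))
        fast = self_attention(Tensor(x[None]), w).data[0]
        np.testing.assert_allclose(fast, _brute_force_attention(x, w), atol=1e-6)

    def test_attention_rows_sum_to_one_all_heads(self):
        rng = np.random.default_rng(3)
        w = AttentionWeights.create(rng, 8, 2)
        x = Tensor(rng.standard_normal((2, 5, 8)))
        attn = attention_matrix(x, w)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)


class TestEncoderForward:
    def test_eval_mode_is_deterministic(self):
        model = _toy_model()
        x = np.random.default_rng(4).standard_normal((2, 5, 4))
        a = model.encoder_forward(x).data
        b = model.encoder_forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_zero_layers_returns_positionally_encoded_input(self):
        model = _toy_model(num_layers=0)
        x = np.random.default_rng(5).standard_normal((2, 5, 4))
        out = model.encoder_forward(x).data
        np.testing.assert_allclose(out, x + positional_encoding(5, 4))

    @pytest.mark.parametrize("b,t,d", [(1, 3, 4), (4, 7, 6)])
    def test_shape_contract(self, b, t, d):
        model = _toy_model(input_dim=d, num_layers=2)
        out = model.encoder_forward(np.zeros((b, t, d)))
        assert out.shape == (b, t, d)

    def test_permutation_equivariance_without_positional_encoding(self):
        model = _toy_model(num_layers=2)
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 6, 4))
        perm = rng.permutation(6)
        base = temporal_average(model.encoder_forward(x, positional=False)).data
        permuted = temporal_average(
            model.encoder_forward(x[:, perm], positional=False)
        ).data
        np.testing.assert_allclose(base, permuted, atol=1e-10)
        # with positional encoding the order matters
        with_pe = temporal_average(model.encoder_forward(x)).data
        with_pe_perm = temporal_average(model.encoder_forward(x[:, perm])).data
        assert not np.allclose(with_pe, with_pe_perm, atol=1e-6)

    def test_nonfinite_activation_names_layer(self):
        model = _toy_model(num_layers=2)
        model.layers[1].ff2.w.data[:] = np.inf
        with pytest.raises(NumericError, match="layer 1"):
            model.encoder_forward(np.ones((1, 3, 4)))


class TestHeadsAndEmbedding:
    def test_temporal_average_cases(self):
        const = np.tile(np.array([1.0, 2.0]), (1, 4, 1))
        np.testing.assert_allclose(temporal_average(Tensor(const)).data, [[1, 2]])
        two = np.array([[[0.0, 0.0], [2.0, 2.0]]])
        np.testing.assert_allclose(temporal_average(Tensor(two)).data, [[1, 1]])

    def test_all_negative_embedding_input_yields_bias(self):
        model = _toy_model()
        v = Tensor(-np.ones((2, 4)))
        out = model.embed_block(v, rng=None).data
        np.testing.assert_allclose(out, np.tile(model.embed_block.linear.b.data,
                                                (2, 1)))

    def test_class_probabilities_normalize(self):
        model = _toy_model()
        x = np.random.default_rng(7).standard_normal((3, 5, 4))
        _, probs = model.predict(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.shape == (3, 5)

    def test_heads_share_embedding_but_not_parameters(self):
        model = _toy_model()
        x = np.random.default_rng(8).standard_normal((2, 5, 4))
        scores_before, _ = model.predict(x)
        model.cls_head.linear.w.data += 10.0
        scores_after, probs_after = model.predict(x)
        np.testing.assert_array_equal(scores_before, scores_after)
        assert probs_after.shape == (2, 5)

    def test_zero_embedding_gives_head_biases(self):
        model = _toy_model()
        e = Tensor(np.zeros((1, 6)))
        np.testing.assert_allclose(model.reg_head(e, rng=None).data[0],
                                   model.reg_head.linear.b.data)


def test_gradients_flow_to_every_parameter():
    model = _toy_model(num_layers=2)
    x = np.random.default_rng(9).standard_normal((3, 4, 4))
    scores, logits = model.forward(x, train=False)
    (scores.sum() + logits.sum()).backward()
    for p in model.params():
        assert p.grad is not None
        assert np.isfinite(p.grad).all()


def test_checkpoint_roundtrip_preserves_predictions():
    model = _toy_model(num_layers=2)
    x = np.random.default_rng(10).standard_normal((2, 5, 4))
    scores, probs = model.predict(x)
    clone = DepressionTransformer.from_state_dict(model.state_dict())
    scores2, probs2 = clone.predict(x)
    np.testing.assert_array_equal(scores, scores2)
    np.testing.assert_array_equal(probs, probs2)


def test_d_model_must_divide_heads():
    with pytest.raises(ValueError):
        EncoderConfig(num_heads=3).resolve_d_model(4)
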