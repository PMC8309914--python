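"""CCC, cross-entropy, multi-task loss and RMSE behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maft.autodiff import Tensor
from maft.losses import (
    DegenerateInputError,
    LossWeights,
    ccc,
    ccc_loss,
    ccc_loss_t,
    cross_entropy,
    cross_entropy_t,
    multitask_loss,
    multitask_loss_t,
    rmse,
)

vectors = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=3, max_size=20
).filter(lambda v: np.asarray(v).std() > 1e-6)


class TestCcc:
    def test_perfect_agreement_is_exactly_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ccc(y, y.copy()) == 1.0

    def test_constant_prediction_at_true_mean_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ccc(y, np.full(3, 2.0)) == 0.0

    def test_antiordered_equal_moments_is_minus_one(self):
        assert ccc(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])) == -1.0

    def test_degenerate_raises_or_returns_one_under_flag(self):
        c = np.full(4, 2.0)
        with pytest.raises(DegenerateInputError):
            ccc(c, c)
        assert ccc(c, c, on_degenerate="one") == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(y=vectors, yh=vectors)
    def test_symmetric_bounded_and_permutation_invariant(self, y, yh):
        n = min(len(y), len(yh))
        y, yh = np.asarray(y[:n]), np.asarray(yh[:n])
        c = ccc(y, yh)
        assert -1.0 <= c <= 1.0
        assert ccc(yh, y) == pytest.approx(c, abs=1e-12)
        perm = np.random.default_rng(0).permutation(n)
        assert ccc(y[perm], yh[perm]) == pytest.approx(c, abs=1e-12)

    def test_equals_pearson_times_bias_factor(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(30)
        yh = 0.5 * y + rng.standard_normal(30)
        r = np.corrcoef(y, yh)[0, 1]
        sy, sh = y.std(), yh.std()
        bias = 2 * sy * sh / (sy**2 + sh**2 + (y.mean() - yh.mean()) ** 2)
        assert ccc(y, yh) == pytest.approx(r * bias, abs=1e-12)

    def test_reduces_to_pearson_for_standardized_inputs(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(100)
        yh = 0.7 * y + 0.3 * rng.standard_normal(100)
        y = (y - y.mean()) / y.std()
        yh = (yh - yh.mean()) / yh.std()
        assert ccc(y, yh) == pytest.approx(np.corrcoef(y, yh)[0, 1], abs=1e-12)


class TestCccLoss:
    def test_identity_with_ccc(self):
        rng = np.random.default_rng(13)
        y, yh = rng.standard_normal(10), rng.standard_normal(10)
        assert ccc_loss(y, yh) + ccc(y, yh) == pytest.approx(1.0, abs=1e-15)

    def test_extremes(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ccc_loss(y, y) == 0.0
        assert ccc_loss(y, y[::-1].copy()) == 2.0

    def test_tensor_loss_matches_numpy_value(self):
        rng = np.random.default_rng(14)
        y, yh = rng.standard_normal(8), rng.standard_normal(8)
        t = ccc_loss_t(Tensor(yh), y)
        assert float(t.data) == pytest.approx(ccc_loss(y, yh), abs=1e-7)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(8)
        yh = rng.standard_normal(8)
        leaf = Tensor(yh, requires_grad=True)
        ccc_loss_t(leaf, y).backward()
        eps = 1e-6
        fd = np.zeros(8)
        for i in range(8):
            up, dn = yh.copy(), yh.copy()
            up[i] += eps
            dn[i] -= eps
            fd[i] = (ccc_loss(y, up) - ccc_loss(y, dn)) / (2 * eps)
        np.testing.assert_allclose(leaf.grad, fd, atol=1e-4)


class TestCrossEntropy:
    def test_one_hot_correct_is_zero(self):
        probs = np.eye(5)[[0, 3, 4]]
        assert cross_entropy(probs, np.array([0, 3, 4])) == pytest.approx(0.0)

    def test_uniform_is_log_five(self):
        probs = np.full((4, 5), 0.2)
        assert cross_entropy(probs, np.array([0, 1, 2, 3])) == pytest.approx(
            np.log(5.0)
        )

    def test_zero_probability_clipped_finite(self):
        probs = np.zeros((1, 5))
        probs[0, 1] = 1.0
        loss = cross_entropy(probs, np.array([0]))
        assert np.isfinite(loss) and loss > 20

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((1, 5), 0.2), np.array([5]))

    def test_logits_path_matches_probability_path(self):
        rng = np.random.default_rng(16)
        logits = rng.standard_normal((6, 5))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 5, size=6)
        assert cross_entropy(logits, labels, from_logits=True) == pytest.approx(
            cross_entropy(probs, labels), abs=1e-12
        )
        t = cross_entropy_t(Tensor(logits), labels)
        assert float(t.data) == pytest.approx(cross_entropy(probs, labels), abs=1e-12)

    def test_minimized_at_empirical_label_distribution(self):
        # over shared row-distributions q, CE of 3 samples with labels
        # (0,0,1) is minimized at q = (2/3, 1/3, 0, 0, 0)
        labels = np.array([0, 0, 1])
        q_star = np.array([2 / 3, 1 / 3, 0, 0, 0])
        best = cross_entropy(np.tile(q_star, (3, 1)), labels)
        rng = np.random.default_rng(17)
        for _ in range(200):
            q = rng.dirichlet(np.ones(5))
            assert cross_entropy(np.tile(q, (3, 1)), labels) >= best - 1e-12


class TestMultitask:
    def test_weight_presets_select_single_terms(self):
        rng = np.random.default_rng(18)
        y, yh = rng.standard_normal(6), rng.standard_normal(6)
        probs = rng.dirichlet(np.ones(5), size=6)
        labels = rng.integers(0, 5, size=6)
        assert multitask_loss(y, yh, probs, labels, LossWeights(1.0, 0.0)) == (
            pytest.approx(ccc_loss(y, yh))
        )
        assert multitask_loss(y, yh, probs, labels, LossWeights(0.0, 1.0)) == (
            pytest.approx(cross_entropy(probs, labels))
        )

    def test_linear_combination(self):
        rng = np.random.default_rng(19)
        y, yh = rng.standard_normal(6), rng.standard_normal(6)
        probs = rng.dirichlet(np.ones(5), size=6)
        labels = rng.integers(0, 5, size=6)
        w = LossWeights(0.9, 0.1)
        expected = 0.9 * ccc_loss(y, yh) + 0.1 * cross_entropy(probs, labels)
        assert multitask_loss(y, yh, probs, labels, w) == pytest.approx(expected)

    def test_tensor_version_consistent(self):
        rng = np.random.default_rng(20)
        y, yh = rng.standard_normal(6), rng.standard_normal(6)
        logits = rng.standard_normal((6, 5))
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        labels = rng.integers(0, 5, size=6)
        w = LossWeights(0.9, 0.1)
        t = multitask_loss_t(Tensor(yh), y, Tensor(logits), labels, w)
        expected = multitask_loss(y, yh, probs, labels, w)
        assert float(t.data) == pytest.approx(expected, abs=1e-7)

    def test_both_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0)


class TestRmse:
    def test_cases(self):
        assert rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5)
        )
        assert rmse(np.array([5.0]), np.array([7.0])) == 2.0
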