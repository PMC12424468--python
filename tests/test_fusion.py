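import numpy as np
import pytest

from lesionfuse._tensor import Tensor, cross_entropy
from lesionfuse.fusion import (BilinearFusion, ConcatFusion,
                               CrossAttentionFusion, FusionConfigError,
                               GatedFusion, HadamardFusion,
                               SelfAttentionFusion, TensorFusion,
                               WeightedConcatFusion, build_fusion,
                               FUSION_METHODS)
from lesionfuse.nn import Adam, Linear


def T(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


# ------------------------------------------------------------ brute oracles
def bilinear_oracle(x, y, W):
    """Triple-loop evaluation of z_i = x^T W_i y."""
    out = np.zeros((x.shape[0], W.shape[0]))
    for b in range(x.shape[0]):
        for i in range(W.shape[0]):
            acc = 0.0
            for j in range(W.shape[1]):
                for k in range(W.shape[2]):
                    acc += x[b, j] * W[i, j, k] * y[b, k]
            out[b, i] = acc
    return out


def cross_attention_oracle(x, y, Wq, Wk, Wv, x_tokens, y_tokens, d):
    """Explicit score -> softmax -> weighted-sum evaluation."""
    B = x.shape[0]
    xt = x.reshape(B, x_tokens, -1)
    yt = y.reshape(B, y_tokens, -1)
    out = np.zeros((B, x_tokens, d))
    for b in range(B):
        q = xt[b] @ Wq
        k = yt[b] @ Wk
        v = yt[b] @ Wv
        for i in range(x_tokens):
            scores = np.array([q[i] @ k[j] for j in range(y_tokens)])
            scores = scores / np.sqrt(d)
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            out[b, i] = sum(a[j] * v[j] for j in range(y_tokens))
    return out.reshape(B, x_tokens * d)


# ------------------------------------------------------------------ contracts
def test_dimension_contract_at_default_widths(rng):
    x = T(rng.normal(size=(2, 512)))
    y = T(rng.normal(size=(2, 256)))
    expected = {"concat": 768, "wconcat": 768, "hadamard": 256,
                "bilinear": 256, "gated": 256}
    for method, dim in expected.items():
        fus = build_fusion(method, 512, 256, rng)
        assert fus.out_dim == dim
        assert fus(x, y).shape == (2, dim)


def test_unknown_method_rejected(rng):
    with pytest.raises(FusionConfigError, match="bogus"):
        build_fusion("bogus", 8, 8, rng)


def test_every_learnable_moves_under_one_optimization_step(rng):
    """All registered fusion parameters are differentiable end-to-end."""
    x = T(rng.normal(size=(8, 16)))
    y = T(rng.normal(size=(8, 8)))
    labels = np.arange(8) % 2
    hyper = {"selfattn": {"x_tokens": 2, "y_tokens": 2, "d_model": 4},
             "crossattn": {"x_tokens": 2, "y_tokens": 2, "d_model": 4},
             "bilinear": {"out_dim": 8}, "tensor": {"proj_dim": 8}}
    for method in FUSION_METHODS:
        fus = build_fusion(method, 16, 8, rng, **hyper.get(method, {}))
        head = Linear(fus.out_dim, 2, rng)
        params = fus.parameters() + head.parameters()
        before = [p.data.copy() for p in params]
        opt = Adam(params, lr=1e-2)
        loss = cross_entropy(head(fus(x, y)), labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        for b, p in zip(before, params):
            assert np.abs(b - p.data).max() > 0, \
                f"{method}: a learnable did not move"


# ----------------------------------------------------------------- operators
class TestConcat:
    def test_stacks_values(self, rng):
        out = ConcatFusion(2, 1)(T([[1, 2]]), T([[3]]))
        np.testing.assert_array_equal(out.data, [[1, 2, 3]])

    def test_first_block_equals_x(self, rng):
        x = rng.normal(size=(3, 5)).astype(np.float32)
        y = rng.normal(size=(3, 2)).astype(np.float32)
        out = ConcatFusion(5, 2)(T(x), T(y)).data
        np.testing.assert_array_equal(out[:, :5], x)
        np.testing.assert_array_equal(out[:, 5:], y)

    def test_non_batched_input_rejected(self):
        with pytest.raises(ValueError):
            ConcatFusion(2, 2)(T([1, 2]), T([3, 4]))


class TestWeightedConcat:
    def test_unit_weights_reduce_to_concat(self, rng):
        x = rng.normal(size=(4, 6)).astype(np.float32)
        y = rng.normal(size=(4, 3)).astype(np.float32)
        wc = WeightedConcatFusion(6, 3)
        plain = ConcatFusion(6, 3)
        np.testing.assert_array_equal(wc(T(x), T(y)).data,
                                      plain(T(x), T(y)).data)

    def test_scalar_weights_applied(self):
        wc = WeightedConcatFusion(1, 1)
        wc.w1.data = np.array(2.0, np.float32)
        wc.w2.data = np.array(0.5, np.float32)
        out = wc(T([[1.0]]), T([[4.0]]))
        np.testing.assert_array_equal(out.data, [[2.0, 2.0]])

    def test_gradient_of_w1_equals_sum_of_x(self, rng):
        x = rng.normal(size=(3, 4)).astype(np.float32)
        y = rng.normal(size=(3, 2)).astype(np.float32)
        wc = WeightedConcatFusion(4, 2)
        wc(T(x), T(y)).sum().backward()
        assert float(wc.w1.grad) == pytest.approx(float(x.sum()), rel=1e-5)
        assert float(wc.w2.grad) == pytest.approx(float(y.sum()), rel=1e-5)


class TestHadamard:
    def test_elementwise_product(self, rng):
        had = HadamardFusion(2, 2, rng)
        had.proj.weight.data = np.eye(2, dtype=np.float32)
        had.proj.bias.data = np.zeros(2, np.float32)
        out = had(T([[1.0, 2.0]]), T([[3.0, 4.0]]))
        np.testing.assert_allclose(out.data, [[3.0, 8.0]])

    def test_all_ones_y_is_multiplicative_identity(self, rng):
        had = HadamardFusion(6, 4, rng)
        x = T(rng.normal(size=(2, 6)))
        xp = had.proj(x).data
        out = had(x, T(np.ones((2, 4)))).data
        np.testing.assert_allclose(out, xp, atol=1e-7)


class TestTensor:
    def test_outer_product_values(self):
        out = TensorFusion.outer(T([[1.0, 2.0]]), T([[3.0, 4.0]])).data[0]
        np.testing.assert_array_equal(out, [[3, 4], [6, 8]])

    def test_bilinearity_sum_identity(self):
        z = TensorFusion.outer(T([[1.0, 2.0]]), T([[3.0, 4.0]])).data[0]
        assert z.sum() == pytest.approx(3.0 * 7.0)

    def test_rank_one_minors_vanish(self, rng):
        x = rng.normal(size=(1, 5)).astype(np.float32)
        y = rng.normal(size=(1, 4)).astype(np.float32)
        z = TensorFusion.outer(T(x), T(y)).data[0]
        for i in range(4):
            for j in range(3):
                minor = z[i, j] * z[i + 1, j + 1] - z[i, j + 1] * z[i + 1, j]
                assert abs(minor) < 1e-5

    def test_projected_output_width(self, rng):
        tf = TensorFusion(6, 4, rng, proj_dim=10)
        assert tf(T(rng.normal(size=(2, 6))),
                  T(rng.normal(size=(2, 4)))).shape == (2, 10)


class TestBilinear:
    def test_single_term_bilinear_form(self, rng):
        bf = BilinearFusion(2, 2, rng, out_dim=1)
        bf.W.data = np.zeros((1, 2, 2), np.float32)
        bf.W.data[0, 0, 0] = 1.0
        out = bf(T([[3.0, 9.0]]), T([[5.0, 7.0]]))
        assert out.data[0, 0] == pytest.approx(15.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            dx, dy, do = rng.integers(2, 6, 3)
            bf = BilinearFusion(int(dx), int(dy), rng, out_dim=int(do))
            x = rng.normal(size=(2, dx)).astype(np.float32)
            y = rng.normal(size=(2, dy)).astype(np.float32)
            got = bf(T(x), T(y)).data
            want = bilinear_oracle(x, y, bf.W.data)
            np.testing.assert_allclose(got, want, atol=1e-6)


class TestGated:
    def test_zero_gate_parameters_give_midpoint(self, rng):
        gf = GatedFusion(4, 3, rng)
        gf.Wx.weight.data[...] = 0.0
        gf.Wy.weight.data[...] = 0.0
        gf.b.data[...] = 0.0
        x = T(rng.normal(size=(2, 4)))
        y = T(rng.normal(size=(2, 3)))
        xp = gf.proj(x).data
        out = gf(x, y).data
        np.testing.assert_array_equal(out, 0.5 * xp + 0.5 * y.data)

    def test_large_bias_saturates_gate_open(self, rng):
        gf = GatedFusion(4, 3, rng)
        gf.Wx.weight.data[...] = 0.0
        gf.Wy.weight.data[...] = 0.0
        gf.b.data[...] = 50.0
        x = T(rng.normal(size=(2, 4)))
        y = T(rng.normal(size=(2, 3)))
        np.testing.assert_allclose(gf(x, y).data, gf.proj(x).data, atol=1e-5)

    def test_gate_strictly_inside_unit_interval(self, rng):
        gf = GatedFusion(4, 3, rng)
        x = T(rng.normal(size=(5, 4)))
        y = T(rng.normal(size=(5, 3)))
        g = (gf.Wx(gf.proj(x)) + gf.Wy(y) + gf.b).sigmoid().data
        assert (g > 0).all() and (g < 1).all()


class TestSelfAttention:
    def test_single_token_attention_weight_is_one(self, rng):
        sa = SelfAttentionFusion(4, 4, rng, x_tokens=1, y_tokens=1,
                                 d_model=3)
        x = rng.normal(size=(2, 4)).astype(np.float32)
        y = rng.normal(size=(2, 4)).astype(np.float32)
        out = sa(T(x), T(y)).data
        np.testing.assert_allclose(out[:, :3], x @ sa.xv.weight.data,
                                   atol=1e-6)
        np.testing.assert_allclose(out[:, 3:], y @ sa.yv.weight.data,
                                   atol=1e-6)

    def test_zero_queries_give_uniform_attention(self, rng):
        sa = SelfAttentionFusion(8, 8, rng, x_tokens=4, y_tokens=4,
                                 d_model=3)
        sa.xq.weight.data[...] = 0.0
        sa.xk.weight.data[...] = 0.0
        x = rng.normal(size=(2, 8)).astype(np.float32)
        attended = sa.attend_x(T(x)).data
        vals = x.reshape(2, 4, 2) @ sa.xv.weight.data
        mean_v = vals.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(attended,
                                   np.broadcast_to(mean_v, attended.shape),
                                   atol=1e-6)

    def test_token_mismatch_rejected(self, rng):
        with pytest.raises(FusionConfigError):
            SelfAttentionFusion(10, 8, rng, x_tokens=3, y_tokens=2)

    def test_attention_rows_are_distributions(self, rng):
        # softmax rows of the score matrix sum to one
        scores = Tensor(rng.normal(size=(2, 4, 5)))
        a = scores.softmax(axis=-1).data
        np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)
        assert (a >= 0).all()


class TestCrossAttention:
    def test_single_clinical_token_returns_value_projection(self, rng):
        ca = CrossAttentionFusion(6, 4, rng, x_tokens=1, y_tokens=1,
                                  d_model=5)
        x = rng.normal(size=(3, 6)).astype(np.float32)
        y = rng.normal(size=(3, 4)).astype(np.float32)
        out = ca(T(x), T(y)).data
        np.testing.assert_array_equal(out, y @ ca.Wv.weight.data)

    def test_identical_keys_give_mean_of_values(self, rng):
        ca = CrossAttentionFusion(6, 8, rng, x_tokens=1, y_tokens=4,
                                  d_model=5)
        y_token = rng.normal(size=(1, 2)).astype(np.float32)
        y = np.tile(y_token, (1, 4))        # all clinical tokens identical
        x = rng.normal(size=(1, 6)).astype(np.float32)
        out = ca(T(x), T(y)).data
        np.testing.assert_allclose(out.ravel(),
                                   (y_token @ ca.Wv.weight.data).ravel(),
                                   atol=1e-6)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            xt, yt = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            wx, wy = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            d = int(rng.integers(2, 5))
            ca = CrossAttentionFusion(xt * wx, yt * wy, rng, x_tokens=xt,
                                      y_tokens=yt, d_model=d)
            x = rng.normal(size=(2, xt * wx)).astype(np.float32)
            y = rng.normal(size=(2, yt * wy)).astype(np.float32)
            got = ca(T(x), T(y)).data
            want = cross_attention_oracle(
                x, y, ca.Wq.weight.data, ca.Wk.weight.data,
                ca.Wv.weight.data, xt, yt, d)
            np.testing.assert_allclose(got, want, atol=1e-6)
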