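"""Gradient correctness and structural properties of the NumPy NN stack."""

import numpy as np
import pytest

from ocufusion.nn.attention import MultiHeadSelfAttention, TokenSelfAttention, softmax
from ocufusion.nn.backbones import (
    InvertedResidual,
    efficientnet_b0,
    mobilenet_v3_small,
    resnet50,
    tiny_cnn,
    vit_b16,
)
from ocufusion.nn.layers import (
    BatchNorm,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Hardsigmoid,
    Hardswish,
    LayerNorm,
    Linear,
    SEUnit,
    Sequential,
    SiLU,
    set_init_rng,
)
from ocufusion.nn.optim import Adam


def finite_diff_check(mod, xshape, eps=1e-3, tol=5e-2, seed=0, n_probe=6):
    """Scale-aware finite-difference check of input and parameter grads.

    Parameters are re-randomized at O(0.3) scale first so pre-activations
    sit away from the kinks of ReLU-family nonlinearities, where central
    differences are meaningless.
    """
    rng = np.random.default_rng(seed)
    for p in mod.parameters():
        p.data = rng.normal(0.0, 0.3, size=p.data.shape).astype(np.float32)
    x = rng.normal(size=xshape).astype(np.float32)
    y0 = mod(x, training=True)
    w = rng.normal(size=y0.shape).astype(np.float32)

    def loss():
        return float((mod(x, training=True) * w).sum())

    mod.zero_grad()
    mod(x, training=True)
    dx = mod.backward(w)
    assert dx.shape == x.shape
    worst = 0.0
    gscale = max(
        (np.abs(p.grad).max() for p in mod.parameters()), default=1.0
    )
    for p in mod.parameters():
        # errors judged relative to the module's dominant gradient scale;
        # float32 central differences are noise below that
        scale = max(np.abs(p.grad).max(), 0.1 * gscale, 1e-3)
        flat, gflat = p.data.reshape(-1), p.grad.reshape(-1)
        for k in rng.choice(flat.size, size=min(n_probe, flat.size), replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            lp = loss()
            flat[k] = orig - eps
            lm = loss()
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - gflat[k]) / max(abs(num), abs(gflat[k]), scale))
    # input gradient at a few coordinates
    for _ in range(n_probe):
        ix = tuple(rng.integers(0, s) for s in xshape)
        xp = x.copy()
        xp[ix] += eps
        lp = float((mod(xp, training=True) * w).sum())
        xp[ix] -= 2 * eps
        lm = float((mod(xp, training=True) * w).sum())
        num = (lp - lm) / (2 * eps)
        worst = max(
            worst, abs(num - dx[ix]) / max(abs(num), abs(dx[ix]), np.abs(dx).max(), 1e-3)
        )
    assert worst < tol, f"gradient mismatch {worst:.3e}"


@pytest.mark.parametrize(
    "build, xshape",
    [
        (lambda: Conv2d(3, 5, 3, stride=2, name="c"), (2, 9, 9, 3)),
        (lambda: Conv2d(4, 4, 3, groups=4, name="dw"), (2, 8, 8, 4)),
        (lambda: Conv2d(4, 4, 5, stride=2, groups=4, name="dw5"), (2, 9, 9, 4)),
        (lambda: Conv2d(4, 6, 1, name="pw"), (2, 5, 5, 4)),
        (lambda: Conv2d(4, 6, 1, stride=2, name="pws"), (2, 5, 5, 4)),
        (lambda: Conv2d(3, 7, 7, stride=2, padding=3, bias=True, name="s7"), (2, 11, 11, 3)),
        (lambda: BatchNorm(5), (4, 3, 3, 5)),
        (lambda: BatchNorm(5), (7, 5)),
        (lambda: LayerNorm(6), (3, 4, 6)),
        (lambda: Linear(5, 4), (3, 5)),
        (lambda: Hardswish(), (3, 5)),
        (lambda: Hardsigmoid(), (3, 5)),
        (lambda: SiLU(), (3, 5)),
        (lambda: TokenSelfAttention(6), (3, 6)),
        (lambda: TokenSelfAttention(6, d_k=6), (3, 4, 6)),
        (lambda: MultiHeadSelfAttention(8, 2), (2, 5, 8)),
        (lambda: InvertedResidual(8, 3, 16, 8, True, "HS", 1, "ir"), (2, 6, 6, 8)),
        (lambda: Sequential(GlobalAvgPool(), Linear(5, 3)), (2, 4, 4, 5)),
    ],
    ids=[
        "conv-general", "conv-depthwise3", "conv-depthwise5", "conv-pointwise",
        "conv-pointwise-strided", "conv-7x7-bias", "batchnorm-2d", "batchnorm-1d",
        "layernorm", "linear", "hardswish", "hardsigmoid", "silu",
        "attention-single-token", "attention-multi-token", "multi-head-attention",
        "inverted-residual", "pool-linear",
    ],
)
def test_backward_matches_finite_differences(build, xshape):
    set_init_rng(np.random.default_rng(99))
    finite_diff_check(build(), xshape)


def test_se_unit_matches_independent_reference():
    """SE gate forward/backward vs a float64 from-scratch implementation."""
    set_init_rng(np.random.default_rng(42))
    mod = SEUnit(8, 3)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 4, 4, 8)).astype(np.float32)
    w = rng.normal(size=(2, 4, 4, 8)).astype(np.float32)
    w1, b1, w2, b2 = [p.data.astype(np.float64) for p in mod.parameters()]

    def ref(w1, b1, w2, b2):
        z = x.astype(np.float64).mean(axis=(1, 2))
        h = np.maximum(z @ w1 + b1, 0)
        g = np.clip((h @ w2 + b2) + 3, 0, 6) / 6
        out = x.astype(np.float64) * g[:, None, None, :]
        return (out * w).sum(), out

    mod.zero_grad()
    y = mod(x, training=True)
    mod.backward(w)
    _, ref_y = ref(w1, b1, w2, b2)
    np.testing.assert_allclose(y, ref_y, atol=1e-5)
    eps = 1e-5
    for pi, p in enumerate(mod.parameters()):
        num = np.zeros_like(p.data, dtype=np.float64)
        for ix in np.ndindex(*p.data.shape):
            args = [a.copy() for a in (w1, b1, w2, b2)]
            args[pi][ix] += eps
            lp, _ = ref(*args)
            args[pi][ix] -= 2 * eps
            lm, _ = ref(*args)
            num[ix] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(p.grad, num, atol=1e-4, rtol=1e-3)


class TestBatchNorm:
    def test_training_output_standardized(self, rng):
        bn = BatchNorm(4)
        x = rng.normal(3.0, 2.0, size=(50, 4)).astype(np.float32)
        y = bn(x, training=True)
        np.testing.assert_allclose(y.mean(axis=0), 0, atol=1e-5)
        np.testing.assert_allclose(y.std(axis=0), 1, atol=1e-3)

    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm(3, momentum=0.5)
        x = rng.normal(2.0, 1.5, size=(200, 3)).astype(np.float32)
        for _ in range(30):
            bn(x, training=True)
        y = bn(x, training=False)
        np.testing.assert_allclose(y.mean(axis=0), 0, atol=0.05)


class TestDropout:
    def test_eval_is_identity(self, rng):
        d = Dropout(0.5)
        x = rng.normal(size=(10, 8)).astype(np.float32)
        np.testing.assert_array_equal(d(x, training=False), x)

    def test_training_preserves_expectation(self, rng):
        d = Dropout(0.3)
        d.rng = np.random.default_rng(0)
        x = np.ones((200, 200), dtype=np.float32)
        y = d(x, training=True)
        assert abs(y.mean() - 1.0) < 0.01


class TestAttention:
    def test_softmax_rows_sum_to_one(self, rng):
        s = softmax(rng.normal(size=(5, 7)), axis=1)
        np.testing.assert_allclose(s.sum(axis=1), 1, atol=1e-6)

    def test_single_token_output_is_value_projection(self, rng):
        set_init_rng(np.random.default_rng(7))
        att = TokenSelfAttention(16)
        f = rng.normal(size=(4, 16)).astype(np.float32)
        out = att(f)
        assert np.array_equal(out, f @ att.w_v.data + att.b_v.data)

    def test_single_token_no_gradient_to_query_key(self, rng):
        set_init_rng(np.random.default_rng(7))
        att = TokenSelfAttention(16)
        f = rng.normal(size=(4, 16)).astype(np.float32)
        att.zero_grad()
        att(f)
        att.backward(np.ones((4, 16), dtype=np.float32))
        assert np.all(att.w_q.grad == 0) and np.all(att.w_k.grad == 0)
        assert np.abs(att.w_v.grad).max() > 0

    def test_multi_token_matches_brute_force(self, rng):
        """Attention weights reproduce softmax(QK^T/sqrt(d_k)) V computed
        independently on a toy feature set."""
        set_init_rng(np.random.default_rng(11))
        att = TokenSelfAttention(4, d_k=4)
        x = rng.normal(size=(3, 3, 4)).astype(np.float32)
        q = x @ att.w_q.data + att.b_q.data
        k = x @ att.w_k.data + att.b_k.data
        v = x @ att.w_v.data + att.b_v.data
        scores = np.einsum("ntd,nsd->nts", q, k) / 2.0
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        a = e / e.sum(axis=-1, keepdims=True)
        ref = np.einsum("nts,nsd->ntd", a, v)
        np.testing.assert_allclose(att(x), ref, atol=1e-5)


class TestBackbones:
    def test_mobilenet_v3_small_parameter_inventory(self):
        """Canonical parameter count with the 1000-way linear removed and
        the 576->1024 embedding retained."""
        assert mobilenet_v3_small().num_parameters() == 1_517_856

    def test_reference_baseline_parameter_counts(self):
        assert resnet50(num_classes=1000).num_parameters() == 25_557_032
        assert efficientnet_b0(num_classes=1000).num_parameters() == 5_288_548
        assert vit_b16(num_classes=1000, image_size=224).num_parameters() == 86_567_656

    @pytest.mark.parametrize("builder", [mobilenet_v3_small, tiny_cnn])
    def test_backbone_forward_shape(self, builder, rng):
        bb = builder(out_dim=32)
        x = rng.normal(size=(2, 64, 64, 3)).astype(np.float32)
        assert bb(x).shape == (2, 32)

    def test_eval_forward_bitwise_repeatable(self, rng):
        bb = tiny_cnn(out_dim=16)
        x = rng.normal(size=(2, 32, 32, 3)).astype(np.float32)
        assert np.array_equal(bb(x, training=False), bb(x, training=False))


class TestAdam:
    def test_matches_reference_update(self, rng):
        from ocufusion.nn.layers import Parameter

        p = Parameter("p", rng.normal(size=(6, 5)))
        ref = p.data.astype(np.float64).copy()
        opt = Adam([p], lr=1e-2)
        m = np.zeros_like(ref)
        v = np.zeros_like(ref)
        for t in range(1, 8):
            g = rng.normal(size=(6, 5))
            p.grad[...] = g.astype(np.float32)
            opt.step()
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            ref -= 1e-2 * (m / (1 - 0.9**t)) / (np.sqrt(v / (1 - 0.999**t)) + 1e-8)
        np.testing.assert_allclose(p.data, ref, atol=1e-5)
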