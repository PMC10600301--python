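"""Layer-level correctness: loop-based oracles and finite differences."""

import numpy as np
import pytest
from scipy.special import log_softmax

from wavefusion import nn


def naive_lead_conv(x, weight, bias, stride, padding):
    """Brute-force per-lead convolution oracle."""
    b, l, ci, h, w = x.shape
    _, co, _, kh, kw = weight.shape
    (sh, sw), (ph, pw) = stride, padding
    xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    out = np.zeros((b, l, co, ho, wo))
    for bi in range(b):
        for li in range(l):
            for c in range(co):
                for i in range(ho):
                    for j in range(wo):
                        patch = xp[bi, li, :, i * sh:i * sh + kh,
                                   j * sw:j * sw + kw]
                        out[bi, li, c, i, j] = (
                            patch * weight[li, c]).sum() + bias[li, c]
    return out


def fd_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def rel_err(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-12)


class TestLeadConv2d:
    @pytest.mark.parametrize("stride,padding", [((1, 1), (0, 0)),
                                                ((2, 1), (2, 1)),
                                                ((2, 2), (1, 0))])
    def test_forward_matches_naive(self, rng, stride, padding):
        conv = nn.LeadConv2d(2, 3, 4, (3, 2), stride, padding, rng)
        x = rng.standard_normal((2, 2, 3, 9, 7))
        got = conv.forward(x)
        want = naive_lead_conv(x, conv.params["weight"], conv.params["bias"],
                               stride, padding)
        assert got.shape == want.shape
        assert rel_err(got, want) < 1e-5

    def test_leads_are_independent(self, rng):
        # zeroing lead 1's input changes only lead 1's output
        conv = nn.LeadConv2d(2, 1, 2, (2, 2), rng=rng)
        x = rng.standard_normal((1, 2, 1, 5, 5))
        full = conv.forward(x)
        x2 = x.copy()
        x2[:, 1] = 0.0
        part = conv.forward(x2)
        assert np.allclose(full[:, 0], part[:, 0])
        assert not np.allclose(full[:, 1], part[:, 1])

    def test_gradients_by_finite_differences(self, rng):
        conv = nn.LeadConv2d(2, 2, 3, (3, 2), (2, 1), (1, 0), rng)
        x = rng.standard_normal((2, 2, 2, 6, 5))
        target = rng.standard_normal(conv.forward(x).shape)

        def loss():
            return 0.5 * ((conv.forward(x) - target) ** 2).sum()

        conv.zero_grad()
        out = conv.forward(x)
        gx = conv.backward(out - target)
        assert rel_err(conv.grads["weight"],
                       fd_grad(loss, conv.params["weight"])) < 1e-5
        assert rel_err(conv.grads["bias"],
                       fd_grad(loss, conv.params["bias"])) < 1e-5
        assert rel_err(gx, fd_grad(loss, x)) < 1e-5


class TestMaxPool:
    def test_forward_matches_naive(self, rng):
        pool = nn.MaxPool2x2()
        x = rng.standard_normal((2, 2, 3, 6, 4))
        out = pool.forward(x)
        for i in range(3):
            for j in range(2):
                want = x[..., 2 * i:2 * i + 2, 2 * j:2 * j + 2].max(
                    axis=(-1, -2))
                assert np.allclose(out[..., i, j], want)

    def test_odd_trailing_row_dropped(self, rng):
        out = nn.MaxPool2x2().forward(rng.standard_normal((1, 1, 1, 5, 7)))
        assert out.shape == (1, 1, 1, 2, 3)

    def test_gradient_routes_to_single_max(self, rng):
        pool = nn.MaxPool2x2()
        x = rng.standard_normal((2, 1, 2, 4, 4))
        out = pool.forward(x)
        g = rng.standard_normal(out.shape)
        gx = pool.backward(g)
        assert np.allclose(gx, pool_backward_naive(x, g))


def pool_backward_naive(x, g):
    gx = np.zeros_like(x)
    b, l, c, h, w = x.shape
    for bi in range(b):
        for li in range(l):
            for ci in range(c):
                for i in range(h // 2):
                    for j in range(w // 2):
                        win = x[bi, li, ci, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
                        k = np.argmax(win)  # first maximum, row-major
                        gx[bi, li, ci, 2 * i + k // 2, 2 * j + k % 2] = \
                            g[bi, li, ci, i, j]
    return gx


class TestSimpleLayers:
    def test_relu(self, rng):
        layer = nn.ReLU()
        x = rng.standard_normal((3, 4))
        out = layer.forward(x)
        assert np.allclose(out, np.maximum(x, 0))
        g = rng.standard_normal(x.shape)
        assert np.allclose(layer.backward(g), g * (x > 0))

    def test_dropout_eval_is_identity(self, rng):
        layer = nn.Dropout(0.5, rng)
        x = rng.standard_normal((4, 4))
        assert layer.forward(x, train=False) is x

    def test_dropout_train_preserves_expectation(self):
        layer = nn.Dropout(0.3, np.random.default_rng(0))
        x = np.ones((200, 200))
        out = layer.forward(x, train=True)
        kept = out > 0
        assert abs(kept.mean() - 0.7) < 0.01
        assert np.allclose(out[kept], 1 / 0.7, atol=1e-6)

    def test_dropout_rate_validation(self):
        with pytest.raises(ValueError):
            nn.Dropout(1.0)

    def test_dense_forward_and_fd_gradients(self, rng):
        dense = nn.Dense(5, 3, rng)
        x = rng.standard_normal((4, 5))
        assert np.allclose(dense.forward(x),
                           x @ dense.params["weight"] + dense.params["bias"])
        target = rng.standard_normal((4, 3))

        def loss():
            return 0.5 * ((dense.forward(x) - target) ** 2).sum()

        dense.zero_grad()
        gx = dense.backward(dense.forward(x) - target)
        assert rel_err(dense.grads["weight"],
                       fd_grad(loss, dense.params["weight"])) < 1e-6
        assert rel_err(gx, fd_grad(loss, x)) < 1e-6

    def test_l2_normalize_unit_norm_and_gradient(self, rng):
        v = rng.standard_normal((6, 4)) * 3
        z = nn.l2_normalize(v)
        assert np.allclose(np.linalg.norm(z, axis=1), 1.0)
        g = rng.standard_normal((6, 4))

        def loss():
            return (nn.l2_normalize(v) * g).sum()

        assert rel_err(nn.l2_normalize_backward(v, g), fd_grad(loss, v)) < 1e-6


class TestBatchNorm:
    def test_train_mode_normalizes(self, rng):
        bn = nn.LeadBatchNorm(2, 3)
        x = rng.standard_normal((8, 2, 3, 4, 4)) * 5 + 2
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 3, 4)), 0, atol=1e-10)
        assert np.allclose(out.std(axis=(0, 3, 4)), 1, atol=1e-3)

    def test_running_stats_track_batches(self, rng):
        bn = nn.LeadBatchNorm(1, 1, momentum=1.0)  # copy the last batch
        x = rng.standard_normal((16, 1, 1, 2, 2)) + 3
        bn.forward(x, train=True)
        assert np.allclose(bn.running_mean, x.mean(), atol=1e-12)
        out = bn.forward(x, train=False)
        assert abs(out.mean()) < 1e-6

    def test_train_backward_fd(self, rng):
        bn = nn.LeadBatchNorm(1, 2)
        x = rng.standard_normal((5, 1, 2, 3, 3))
        g = rng.standard_normal(x.shape)

        def loss():
            bn2 = nn.LeadBatchNorm(1, 2)
            bn2.params = bn.params
            return (bn2.forward(x, train=True) * g).sum()

        bn.zero_grad()
        bn.forward(x, train=True)
        gx = bn.backward(g)
        assert rel_err(gx, fd_grad(loss, x)) < 1e-5
        assert rel_err(bn.grads["gamma"],
                       fd_grad(loss, bn.params["gamma"])) < 1e-6


class TestLossesAndOptimizers:
    def test_cross_entropy_matches_log_softmax(self, rng):
        logits = rng.standard_normal((6, 2)) * 3
        labels = rng.integers(0, 2, size=6)
        loss, grad = nn.cross_entropy(logits, labels)
        want = -log_softmax(logits, axis=1)[np.arange(6), labels].mean()
        assert loss == pytest.approx(want, rel=1e-12)

    def test_cross_entropy_gradient_fd(self, rng):
        logits = rng.standard_normal((4, 2))
        labels = np.array([0, 1, 1, 0])

        def loss():
            return nn.cross_entropy(logits, labels)[0]

        _, grad = nn.cross_entropy(logits, labels)
        assert rel_err(grad, fd_grad(loss, logits)) < 1e-6

    def test_sgd_descends_a_quadratic(self):
        layer = nn.Dense(1, 1)
        layer.params["weight"][:] = 4.0
        layer.params["bias"][:] = 0.0
        opt = nn.SGD([layer], lr=0.1)
        for _ in range(100):
            opt.zero_grad()
            layer.grads["weight"][:] = layer.params["weight"]  # d/dw w^2/2
            opt.step()
        assert abs(layer.params["weight"][0, 0]) < 1e-3

    def test_sgd_weight_decay_skips_bias(self):
        layer = nn.Dense(1, 1)
        layer.params["weight"][:] = 1.0
        layer.params["bias"][:] = 1.0
        opt = nn.SGD([layer], lr=0.5, weight_decay=1.0)
        opt.zero_grad()
        opt.step()
        assert layer.params["weight"][0, 0] == pytest.approx(0.5)
        assert layer.params["bias"][0] == pytest.approx(1.0)

    def test_adam_descends_a_quadratic(self):
        layer = nn.Dense(1, 1)
        layer.params["weight"][:] = 4.0
        opt = nn.Adam([layer], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            layer.grads["weight"][:] = layer.params["weight"]
            opt.step()
        assert abs(layer.params["weight"][0, 0]) < 1e-2
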