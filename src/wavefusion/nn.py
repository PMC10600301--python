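"""Minimal NumPy neural-network layers with explicit backpropagation.

The fusion network is small (a few tens of thousands of parameters) and
runs on desk-scale batches, so the layers here are written directly on
NumPy arrays.  Convolutions operate on ``(batch, lead, channel, H, W)``
tensors with an independent weight bank per lead, which vectorizes the
"one lightweight CNN per lead" design into single einsum calls.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``grads``; ``backward`` returns the
gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-style uniform initialization for ReLU networks."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base: parameter and gradient dicts, no-op by default."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class LeadConv2d(Layer):
    """2-D convolution with an independent kernel bank per lead.

    Input ``(B, L, C_in, H, W)`` -> output ``(B, L, C_out, H', W')`` where
    lead ``l`` is convolved with its own ``weight[l]``.
    """

    def __init__(self, n_leads: int, c_in: int, c_out: int,
                 kernel: tuple[int, int], stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] = (0, 0),
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        fan_in = c_in * kh * kw
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.params["weight"] = kaiming_uniform(
            rng, (n_leads, c_out, c_in, kh, kw), fan_in)
        self.params["bias"] = rng.uniform(
            -1 / np.sqrt(fan_in), 1 / np.sqrt(fan_in), size=(n_leads, c_out))
        self.zero_grad()

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        b, l, ci, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw),
                                                       axis=(3, 4))
        win = win[:, :, :, ::sh, ::sw]          # (B,L,Ci,Ho,Wo,kh,kw)
        ho, wo = win.shape[3], win.shape[4]
        # im2col per lead, then one BLAS matmul batched over leads
        cols = np.ascontiguousarray(win.transpose(1, 0, 3, 4, 2, 5, 6)
                                    ).reshape(l, b * ho * wo, ci * kh * kw)
        co = self.params["weight"].shape[1]
        wmat = self.params["weight"].reshape(l, co, ci * kh * kw)
        out = cols @ wmat.transpose(0, 2, 1)    # (L, B*Ho*Wo, Co)
        self._cols, self._xshape, self._oshape = cols, x.shape, (ho, wo)
        out = out.reshape(l, b, ho, wo, co).transpose(1, 0, 4, 2, 3)
        return out + self.params["bias"][None, :, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        b, l, ci, h, w = self._xshape
        ho, wo = self._oshape
        co = gout.shape[2]
        g2 = np.ascontiguousarray(gout.transpose(1, 0, 3, 4, 2)
                                  ).reshape(l, b * ho * wo, co)
        dw = g2.transpose(0, 2, 1) @ self._cols          # (L, Co, Ci*kh*kw)
        self.grads["weight"] += dw.reshape(l, co, ci, kh, kw)
        self.grads["bias"] += g2.sum(axis=1)
        wmat = self.params["weight"].reshape(l, co, ci * kh * kw)
        dcols = g2 @ wmat                                # (L, B*Ho*Wo, ...)
        dwin = dcols.reshape(l, b, ho, wo, ci, kh, kw
                             ).transpose(1, 0, 4, 2, 3, 5, 6)
        gx = np.zeros((b, l, ci, h + 2 * ph, w + 2 * pw), dtype=gout.dtype)
        for y in range(kh):
            for x_ in range(kw):
                gx[:, :, :, y:y + sh * ho:sh, x_:x_ + sw * wo:sw] += \
                    dwin[..., y, x_]
        self._cols = None
        return gx[:, :, :, ph:ph + h, pw:pw + w]


class MaxPool2x2(Layer):
    """Non-overlapping 2x2 max pooling (trailing odd row/col dropped).

    Gradient routes to the first maximal element of each window in
    (top-left, top-right, bottom-left, bottom-right) order.
    """

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h2, w2 = x.shape[3] // 2, x.shape[4] // 2
        quads = [x[:, :, :, dy:dy + 2 * h2:2, dx:dx + 2 * w2:2]
                 for dy, dx in self._OFFSETS]
        out = np.maximum.reduce(quads)
        self._quads, self._out, self._inshape = quads, out, x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, l, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        gx = np.zeros((b, l, c, h, w), dtype=gout.dtype)
        taken = np.zeros(gout.shape, dtype=bool)
        for quad, (dy, dx) in zip(self._quads, self._OFFSETS):
            mask = (quad == self._out) & ~taken
            gx[:, :, :, dy:dy + 2 * h2:2, dx:dx + 2 * w2:2] = gout * mask
            taken |= mask
        self._quads = self._out = None
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = ((u >= self.rate) / np.float32(1 - self.rate)
                      ).astype(x.dtype, copy=False)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class LeadBatchNorm(Layer):
    """Batch normalization with independent statistics per (lead, channel).

    Normalizes over the (batch, H, W) axes of a ``(B, L, C, H, W)`` input;
    keeps exponential running statistics for eval mode.
    """

    def __init__(self, n_leads: int, n_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones((n_leads, n_channels))
        self.params["beta"] = np.zeros((n_leads, n_channels))
        self.running_mean = np.zeros((n_leads, n_channels))
        self.running_var = np.ones((n_leads, n_channels))
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, :, None, None]
        v = var[None, :, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._std = np.sqrt(v + self.eps)
        self._train = train
        self._n = x.shape[0] * x.shape[3] * x.shape[4]
        g = self.params["gamma"][None, :, :, None, None]
        b = self.params["beta"][None, :, :, None, None]
        return g * self._xhat + b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        axes = (0, 3, 4)
        self.grads["gamma"] += (gout * self._xhat).sum(axis=axes)
        self.grads["beta"] += gout.sum(axis=axes)
        g = self.params["gamma"][None, :, :, None, None]
        gxhat = gout * g
        if not self._train:
            return gxhat / self._std
        n = self._n
        sum_g = gxhat.sum(axis=axes, keepdims=True)
        sum_gx = (gxhat * self._xhat).sum(axis=axes, keepdims=True)
        return (gxhat - sum_g / n - self._xhat * sum_gx / n) / self._std


class Dense(Layer):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["weight"] = kaiming_uniform(rng, (d_in, d_out), d_in)
        self.params["bias"] = rng.uniform(
            -1 / np.sqrt(d_in), 1 / np.sqrt(d_in), size=d_out)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = gout.reshape(-1, gout.shape[-1])
        self.grads["weight"] += x2.T @ g2
        self.grads["bias"] += g2.sum(axis=0)
        return gout @ self.params["weight"].T


def l2_normalize(v: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Row-wise projection onto the unit sphere."""
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.maximum(norm, eps)


def l2_normalize_backward(v: np.ndarray, gout: np.ndarray,
                          eps: float = 1e-12) -> np.ndarray:
    norm = np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), eps)
    z = v / norm
    return (gout - z * (z * gout).sum(axis=-1, keepdims=True)) / norm


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class SGD:
    """Plain stochastic gradient descent with optional weight decay."""

    def __init__(self, layers: list[Layer], lr: float,
                 weight_decay: float = 0.0) -> None:
        self.layers, self.lr, self.weight_decay = layers, lr, weight_decay

    def step(self) -> None:
        for layer in self.layers:
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and k not in ("bias", "beta"):
                    g = g + self.weight_decay * p
                p -= self.lr * g

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


class Adam:
    """Adam with decoupled-style L2 added to the gradient (classic Adam)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.layers, self.lr = layers, lr
        self.b1, self.b2 = betas
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in la.params.items()}
                  for la in layers]
        self.v = [{k: np.zeros_like(p) for k, p in la.params.items()}
                  for la in layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and k not in ("bias", "beta"):
                    g = g + self.weight_decay * p
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1 ** self.t)
                vhat = self.v[i][k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
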