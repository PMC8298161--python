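"""Neural-network building blocks with explicit forward/backward passes.

Tensors are NCHW float32/float64 numpy arrays.  Each layer caches what its
backward pass needs during ``forward(train=True)``; ``backward`` consumes the
upstream gradient and returns the gradient with respect to the layer input
while accumulating parameter gradients in ``.g``.

Convolution is the ReLU(sum_m v_m * w_n + b_n) map of a standard CNN layer;
the residual block computes H(x) = F(x, theta) + x, the stacked branch plus
an identity shortcut (a 1x1 projection when shape changes).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


class Layer:
    """Base layer; parameters in ``.p`` (dict), gradients in ``.g``."""

    #: when True, forward/backward keep this layer's output and its gradient
    store_output: bool = False

    def __init__(self):
        self.p: dict = {}
        self.g: dict = {}
        self.last_output = None
        self.last_output_grad = None

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def sublayers(self):
        return []

    def iter_layers(self):
        yield self
        for sub in self.sublayers():
            yield from sub.iter_layers()

    def _maybe_store_out(self, out):
        if self.store_output:
            self.last_output = out

    def _maybe_store_grad(self, dout):
        if self.store_output:
            self.last_output_grad = dout


class Conv2d(Layer):
    def __init__(self, cin, cout, kernel, stride=1, pad=0, bias=True, rng=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, kernel
        self.stride, self.pad = stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        self.p["W"] = (rng.standard_normal((cout, cin, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        if bias:
            self.p["b"] = np.zeros(cout, dtype=np.float32)

    def _windows(self, xp):
        sw = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return sw[:, :, :: self.stride, :: self.stride]

    def forward(self, x, train=True):
        self.x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self.xp = xp if train else None
        sw = self._windows(xp)
        out = np.einsum("nchwij,ocij->nohw", sw, self.p["W"], optimize=True)
        if "b" in self.p:
            out += self.p["b"][None, :, None, None]
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        sw = self._windows(self.xp)
        self.g["W"] = np.einsum("nchwij,nohw->ocij", sw, dout, optimize=True)
        if "b" in self.p:
            self.g["b"] = dout.sum(axis=(0, 2, 3))
        n, _, H, W = self.x_shape
        dxp = np.zeros_like(self.xp)
        Ho, Wo = dout.shape[2], dout.shape[3]
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += np.einsum(
                    "nohw,oc->nchw", dout, self.p["W"][:, :, i, j], optimize=True
                )
        if self.pad:
            return dxp[:, :, self.pad : self.pad + H, self.pad : self.pad + W]
        return dxp


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.p["W"] = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.p["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=True):
        self.x = x if train else None
        out = x @ self.p["W"].T + self.p["b"]
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        self.g["W"] = dout.T @ self.x
        self.g["b"] = dout.sum(axis=0)
        return dout @ self.p["W"]


class ReLU(Layer):
    def forward(self, x, train=True):
        self.mask = x > 0
        out = np.where(self.mask, x, 0.0)
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        return np.where(self.mask, dout, 0.0)


class MaxPool2d(Layer):
    """2x2 (default) non-overlapping max pooling; trailing rows/cols cropped."""

    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=True):
        p = self.pool
        n, c, H, W = x.shape
        Ho, Wo = H // p, W // p
        xr = x[:, :, : Ho * p, : Wo * p].reshape(n, c, Ho, p, Wo, p)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, Ho, Wo, p * p)
        self.arg = xr.argmax(axis=-1)
        self.in_shape = (n, c, H, W)
        out = np.take_along_axis(xr, self.arg[..., None], axis=-1)[..., 0]
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        p = self.pool
        n, c, H, W = self.in_shape
        Ho, Wo = H // p, W // p
        flat = np.zeros((n, c, Ho, Wo, p * p), dtype=dout.dtype)
        np.put_along_axis(flat, self.arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, H, W), dtype=dout.dtype)
        dx[:, :, : Ho * p, : Wo * p] = (
            flat.reshape(n, c, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, Ho * p, Wo * p)
        )
        return dx


class AvgPool2d(Layer):
    """Non-overlapping mean pooling; preserves within-window sums, which keeps
    allele-frequency-like signals that a max would saturate away."""

    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=True):
        p = self.pool
        n, c, H, W = x.shape
        Ho, Wo = H // p, W // p
        self.in_shape = (n, c, H, W)
        out = x[:, :, : Ho * p, : Wo * p].reshape(n, c, Ho, p, Wo, p).mean(axis=(3, 5))
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        p = self.pool
        n, c, H, W = self.in_shape
        Ho, Wo = H // p, W // p
        dx = np.zeros((n, c, H, W), dtype=dout.dtype)
        dx[:, :, : Ho * p, : Wo * p] = np.repeat(np.repeat(dout, p, axis=2), p, axis=3) / (p * p)
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalisation.

    ``frozen=True`` makes the layer use its running statistics even during a
    caching (train=True) pass, so a backward pass differentiates the frozen
    affine map — needed when saliency gradients are taken in inference mode.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.frozen = False
        self.p["gamma"] = np.ones(channels, dtype=np.float32)
        self.p["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, train=True):
        if train and not self.frozen:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self.invstd = 1.0 / np.sqrt(var + self.eps)
            self.was_frozen = False
        else:
            mean = self.running_mean
            self.invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            self.was_frozen = True
        self.xhat = ((x - mean[None, :, None, None]) * self.invstd[None, :, None, None]).astype(
            np.float32
        )
        out = self.p["gamma"][None, :, None, None] * self.xhat + self.p["beta"][None, :, None, None]
        self._maybe_store_out(out)
        return out.astype(x.dtype)

    def backward(self, dout):
        self._maybe_store_grad(dout)
        self.g["gamma"] = (dout * self.xhat).sum(axis=(0, 2, 3))
        self.g["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.p["gamma"][None, :, None, None]
        if self.was_frozen:
            dx = dxhat * self.invstd[None, :, None, None]
            return dx.astype(dout.dtype)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        t1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        t2 = (dxhat * self.xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (self.invstd[None, :, None, None] / m) * (m * dxhat - t1 - self.xhat * t2)
        return dx.astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=True):
        self.in_shape = x.shape
        out = x.reshape(x.shape[0], -1)
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        return dout.reshape(self.in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self.in_shape = x.shape
        out = x.mean(axis=(2, 3))
        self._maybe_store_out(out)
        return out

    def backward(self, dout):
        self._maybe_store_grad(dout)
        n, c, H, W = self.in_shape
        return np.broadcast_to(dout[:, :, None, None], self.in_shape) / (H * W)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def sublayers(self):
        return self.layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """H(x) = F(x, theta) + shortcut(x), optionally followed by ReLU.

    F is conv3x3(stride)-BN-ReLU-conv3x3-BN (BN optional); the shortcut is the
    identity when shape is preserved, else a strided 1x1 projection (+BN).
    ``post_activation=False`` exposes the raw additive form, under which a
    stack of K dimension-preserving blocks satisfies
    x_K = x_0 + sum_r F(x_{r-1}).
    """

    def __init__(self, cin, cout, stride=1, use_bn=True, post_activation=True, rng=None):
        super().__init__()
        self.post_activation = post_activation
        bias = not use_bn
        branch = [Conv2d(cin, cout, 3, stride=stride, pad=1, bias=bias, rng=rng)]
        if use_bn:
            branch.append(BatchNorm2d(cout))
        branch.append(ReLU())
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, bias=bias, rng=rng)
        branch.append(self.conv2)
        if use_bn:
            branch.append(BatchNorm2d(cout))
        self.branch = Sequential(*branch)
        if stride != 1 or cin != cout:
            short = [Conv2d(cin, cout, 1, stride=stride, pad=0, bias=bias, rng=rng)]
            if use_bn:
                short.append(BatchNorm2d(cout))
            self.shortcut = Sequential(*short)
        else:
            self.shortcut = None

    def sublayers(self):
        subs = [self.branch]
        if self.shortcut is not None:
            subs.append(self.shortcut)
        return subs

    def forward(self, x, train=True):
        b = self.branch.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        y = b + s
        if self.post_activation:
            self.mask = y > 0
            y = np.where(self.mask, y, 0.0)
        self._maybe_store_out(y)
        return y

    def backward(self, dout):
        self._maybe_store_grad(dout)
        if self.post_activation:
            dout = np.where(self.mask, dout, 0.0)
        db = self.branch.backward(dout)
        ds = self.shortcut.backward(dout) if self.shortcut is not None else dout
        return db + ds


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    return loss, (probs - onehot) / n


class Adam:
    """Adam with classic L2 regularisation added to the gradient."""

    def __init__(self, layers, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.slots = []
        for layer in layers:
            for name in layer.p:
                self.slots.append((layer, name))
        self.m = [np.zeros_like(layer.p[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.p[name]) for layer, name in self.slots]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for idx, (layer, name) in enumerate(self.slots):
            if name not in layer.g:
                continue
            grad = layer.g[name]
            # bias/offset parameters are conventionally not decayed
            if self.weight_decay and name in ("W",):
                grad = grad + self.weight_decay * layer.p[name]
            self.m[idx] = b1 * self.m[idx] + (1 - b1) * grad
            self.v[idx] = b2 * self.v[idx] + (1 - b2) * grad * grad
            mhat = self.m[idx] / (1 - b1**self.t)
            vhat = self.v[idx] / (1 - b2**self.t)
            layer.p[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.p[name].dtype
            )
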