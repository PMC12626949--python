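"""Minimal NumPy neural-network engine used by the window classifier.

Implements exactly the pieces the architecture needs — 3×3 "same"
2-D convolution (via im2col), batch normalisation, inverted dropout,
dense layers with L2 weight penalty, sigmoid/binary-cross-entropy head,
Adam — plus a training loop with reduce-LR-on-plateau and early stopping
with best-weight restoration.  Everything is float32 and driven by a
single ``numpy.random.Generator``, so training is deterministic for a
fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def l2_penalty(self):
        return 0.0


class Conv2DSame(Layer):
    """3×3 stride-1 convolution with zero "same" padding on both axes."""

    def __init__(self, c_in, filters, rng, kernel=3):
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        self.filters = filters
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / (fan_in + filters))  # Glorot uniform
        W = rng.uniform(-limit, limit, size=(kernel * kernel * c_in, filters))
        self.W = W.astype(DTYPE)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.W, self.gW], [self.b, self.gb]]

    def _im2col(self, xpad, H, W):
        k = self.kernel
        B = xpad.shape[0]
        cols = np.empty((B, H, W, k * k * self.c_in), dtype=DTYPE)
        i = 0
        for dh in range(k):
            for dw in range(k):
                cols[..., i:i + self.c_in] = xpad[:, dh:dh + H, dw:dw + W, :]
                i += self.c_in
        return cols

    def forward(self, x, training):
        B, H, W, _ = x.shape
        p = self.kernel // 2
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = self._im2col(xpad, H, W)
        self._cache = (cols, x.shape)
        out = cols.reshape(-1, cols.shape[-1]) @ self.W + self.b
        return out.reshape(B, H, W, self.filters)

    def backward(self, dout):
        cols, xshape = self._cache
        B, H, W, _ = xshape
        k, p = self.kernel, self.kernel // 2
        dflat = dout.reshape(-1, self.filters)
        self.gW[...] = cols.reshape(-1, cols.shape[-1]).T @ dflat
        self.gb[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(B, H, W, k * k * self.c_in)
        dxpad = np.zeros((B, H + 2 * p, W + 2 * p, self.c_in), dtype=DTYPE)
        i = 0
        for dh in range(k):
            for dw in range(k):
                dxpad[:, dh:dh + H, dw:dw + W, :] += dcols[..., i:i + self.c_in]
                i += self.c_in
        self._cache = None
        return dxpad[:, p:p + H, p:p + W, :]


class BatchNorm(Layer):
    """Per-feature batch normalisation over all leading axes."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.params = [[self.gamma, self.ggamma], [self.beta, self.gbeta]]

    def forward(self, x, training):
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, shape)
        return (self.gamma * xhat + self.beta).reshape(shape).astype(DTYPE)

    def backward(self, dout):
        xhat, inv_std, shape = self._cache
        dflat = dout.reshape(-1, shape[-1])
        m = dflat.shape[0]
        self.ggamma[...] = (dflat * xhat).sum(axis=0)
        self.gbeta[...] = dflat.sum(axis=0)
        dxhat = dflat * self.gamma
        dx = (inv_std / m) * (m * dxhat - dxhat.sum(axis=0)
                              - xhat * (dxhat * xhat).sum(axis=0))
        self._cache = None
        return dx.reshape(shape).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional L2 kernel penalty (λ·Σw²)."""

    def __init__(self, n_in, n_out, rng, l2=0.0):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.l2 = l2
        self.params = [[self.W, self.gW], [self.b, self.gb]]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.gW[...] = self._x.T @ dout
        if self.l2:
            self.gW += 2.0 * self.l2 * self.W
        self.gb[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def l2_penalty(self):
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2))


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def l2_penalty(self):
        return sum(layer.l2_penalty() for layer in self.layers)

    def get_weights(self):
        w = [p[0].copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                w.append(layer.running_mean.copy())
                w.append(layer.running_var.copy())
        return w

    def set_weights(self, weights):
        weights = list(weights)
        k = len(self.params)
        for pair, w in zip(self.params, weights[:k]):
            pair[0][...] = w
        i = k
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = weights[i]
                layer.running_var[...] = weights[i + 1]
                i += 2


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits, y):
    """Stable binary cross-entropy; returns (mean loss, dL/dlogits)."""
    z = logits.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / len(y)).astype(DTYPE).reshape(-1, 1)
    return float(loss), grad, p


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))
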