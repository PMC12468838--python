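"""Minimal numpy neural-network layers with explicit backprop.

Only what the encoders and fusion head need: dense, 1-D/2-D convolution
(cross-correlation, 'same' padding), max pooling, global average pooling,
batch normalization, dropout, and an Adam optimizer.  Layers cache their
forward inputs and accumulate parameter gradients in ``Param.grad``;
``params_to_vector`` / ``vector_to_params`` flatten parameters for the
federated shared-head arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "ReLU", "Conv2D", "MaxPool2D", "GAP2D",
    "Conv1D", "MaxPool1D", "GlobalAvgPool1D", "BatchNorm1D", "Dropout",
    "Sequential", "Adam", "params_to_vector", "vector_to_params",
    "cosine_lr",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init; biases start at zero
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _pad_same(x, k, axes):
    pad = [(0, 0)] * x.ndim
    for ax in axes:
        pad[ax] = (k // 2, k // 2)
    return np.pad(x, pad)


class Conv2D(Layer):
    """3x3-style 2-D cross-correlation with 'same' padding.

    Input layout (B, H, W, C_in); kernel (k, k, C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, input_grad: bool = True):
        fan_in = k * k * c_in
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride = k, stride
        self.input_grad = input_grad   # False for the stack's first layer

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        k, s = self.k, self.stride
        xp = _pad_same(x, k, axes=(1, 2))
        # windows: (B, Ho, Wo, C, k, k); reshape in (C, k, k) order avoids a
        # permuted copy, so the kernel is stored matching that layout
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]
        B, Ho, Wo = win.shape[:3]
        col = win.reshape(B * Ho * Wo, x.shape[3] * k * k)
        self._cache = (x.shape, col, Ho, Wo)
        Wm = self.W.value.transpose(2, 0, 1, 3).reshape(x.shape[3] * k * k, -1)
        out = col @ Wm + self.b.value
        return out.reshape(B, Ho, Wo, -1)

    def backward(self, dout):
        (xshape, col, Ho, Wo) = self._cache
        B, H, W, C = xshape
        k, s = self.k, self.stride
        dflat = dout.reshape(B * Ho * Wo, -1)
        self.W.grad += (col.T @ dflat).reshape(C, k, k, -1).transpose(1, 2, 0, 3)
        self.b.grad += dflat.sum(axis=0)
        if not self.input_grad:
            return None
        Wm = self.W.value.transpose(2, 0, 1, 3).reshape(C * k * k, -1)
        dcol = (dflat @ Wm.T).reshape(B, Ho, Wo, C, k, k)
        dxp = np.zeros((B, H + 2 * (k // 2), W + 2 * (k // 2), C))
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + s * Ho:s, dj:dj + s * Wo:s] += dcol[:, :, :, :, di, dj]
        p = k // 2
        return dxp[:, p:p + H, p:p + W]


class MaxPool2D(Layer):
    """Non-overlapping max pooling (window = stride = size)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=True):
        s = self.size
        B, H, W, C = x.shape
        Ho, Wo = H // s, W // s
        xt = x[:, :Ho * s, :Wo * s].reshape(B, Ho, s, Wo, s, C)
        out = xt.max(axis=(2, 4))
        self._cache = (x.shape, xt, out)
        return out

    def backward(self, dout):
        xshape, xt, out = self._cache
        s = self.size
        mask = xt == out[:, :, None, :, None, :]
        # distribute among ties equally to keep backward deterministic
        mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        dxt = mask * dout[:, :, None, :, None, :]
        B, H, W, C = xshape
        dx = np.zeros(xshape)
        Ho, Wo = H // s, W // s
        dx[:, :Ho * s, :Wo * s] = dxt.reshape(B, Ho * s, Wo * s, C)
        return dx


class GAP2D(Layer):
    """Global average pooling over the spatial dimensions."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        B, H, W, C = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (H * W), self._shape).copy()


class Conv1D(Layer):
    """1-D cross-correlation, 'same' padding.  Input (B, L, C_in)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * c_in
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        k = self.k
        xp = _pad_same(x, k, axes=(1,))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
        B, L = win.shape[:2]
        col = win.transpose(0, 1, 3, 2).reshape(B * L, k * x.shape[2])
        self._cache = (x.shape, col, L)
        out = col @ self.W.value.reshape(k * x.shape[2], -1) + self.b.value
        return out.reshape(B, L, -1)

    def backward(self, dout):
        xshape, col, L = self._cache
        B, _, C = xshape
        k = self.k
        dflat = dout.reshape(B * L, -1)
        self.W.grad += (col.T @ dflat).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcol = (dflat @ self.W.value.reshape(k * C, -1).T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + 2 * (k // 2), C))
        for di in range(k):
            dxp[:, di:di + L] += dcol[:, :, di]
        p = k // 2
        return dxp[:, p:p + L]


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=True):
        s = self.size
        B, L, C = x.shape
        Lo = L // s
        xt = x[:, :Lo * s].reshape(B, Lo, s, C)
        out = xt.max(axis=2)
        self._cache = (x.shape, xt, out)
        return out

    def backward(self, dout):
        xshape, xt, out = self._cache
        s = self.size
        mask = xt == out[:, :, None, :]
        mask = mask / np.maximum(mask.sum(axis=2, keepdims=True), 1)
        dxt = mask * dout[:, :, None, :]
        B, L, C = xshape
        dx = np.zeros(xshape)
        Lo = L // s
        dx[:, :Lo * s] = dxt.reshape(B, Lo * s, C)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dout):
        B, L, C = self._shape
        return np.broadcast_to(dout[:, None, :] / L, self._shape).copy()


class BatchNorm1D(Layer):
    """Batch normalization over features; running stats for inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std, x.shape[0], train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, std, B, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat / std
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def params_to_vector(params: list[Param]) -> np.ndarray:
    return np.concatenate([p.value.ravel() for p in params]) if params else np.zeros(0)


def vector_to_params(vec: np.ndarray, params: list[Param]) -> None:
    off = 0
    for p in params:
        size = p.value.size
        p.value = vec[off:off + size].reshape(p.value.shape).copy()
        off += size
    if off != vec.size:
        raise ValueError(f"vector length {vec.size} does not match parameters ({off})")


def cosine_lr(base: float, t: int, t_max: int, lr_min: float = 1e-6) -> float:
    """Cosine-annealed learning rate over ``t_max`` global rounds."""
    if t_max <= 1:
        return base
    return lr_min + 0.5 * (base - lr_min) * (1.0 + np.cos(np.pi * t / (t_max - 1)))
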