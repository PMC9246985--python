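"""Minimal numpy neural-network engine.

Hand-written forward/backward passes for the small set of layers the two
networks need: dense layers, dilated 1-D convolutions, gated convolution
blocks (tanh * sigmoid, with residual connection), densely connected
convolution layers (channel concatenation), a bidirectional recurrent module,
average pooling and the usual activations, plus an ADAM optimizer.  All
randomness flows through an explicit numpy Generator, so training is
bit-reproducible on a fixed seed and a single thread.

Shapes: sequence tensors are (batch, length, channels); dense tensors are
(batch, features).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "GatedConvBlock",
    "DenseConv",
    "BiRNN",
    "AvgPool1D",
    "Flatten",
    "Reshape",
    "Activation",
    "FixedLinear",
    "Sequential",
    "Adam",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _act(name, x):
    if name is None or name == "linear":
        return x
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh(x)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name, y):
    # gradients expressed through the activation output y
    if name is None or name == "linear":
        return 1.0
    if name == "relu":
        return (y > 0).astype(y.dtype)
    if name == "tanh":
        return 1.0 - y * y
    if name == "sigmoid":
        return y * (1.0 - y)
    raise ValueError(name)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError


class Activation(Layer):
    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x):
        self._y = _act(self.name, x)
        return self._y

    def backward(self, g):
        return g * _act_grad(self.name, self._y)


class Dense(Layer):
    def __init__(self, n_in, n_out, activation=None, rng=None):
        super().__init__()
        self.activation = activation
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.grads = [self.gW, self.gb]

    def forward(self, x):
        self._x = x
        self._y = _act(self.activation, x @ self.W + self.b)
        return self._y

    def backward(self, g):
        g = g * _act_grad(self.activation, self._y)
        self.gW[...] = self._x.reshape(-1, self.W.shape[0]).T @ g.reshape(-1, self.W.shape[1])
        self.gb[...] = g.reshape(-1, self.b.size).sum(axis=0)
        return g @ self.W.T


class Conv1D(Layer):
    """Same-padded dilated 1-D convolution over (batch, length, channels)."""

    def __init__(self, c_in, c_out, kernel, dilation=1, activation=None, rng=None):
        super().__init__()
        assert kernel % 2 == 1, "odd kernels only"
        self.k, self.d, self.c_in, self.c_out = kernel, dilation, c_in, c_out
        self.activation = activation
        self.W = _glorot(rng, (kernel * c_in, c_out), kernel * c_in, c_out)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.grads = [self.gW, self.gb]

    def _im2col(self, x):
        B, L, C = x.shape
        p = self.d * (self.k - 1) // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=x.dtype)
        xp[:, p : p + L] = x
        cols = np.empty((B, L, self.k, C), dtype=x.dtype)
        for j in range(self.k):
            cols[:, :, j] = xp[:, j * self.d : j * self.d + L]
        return cols.reshape(B, L, self.k * C)

    def forward(self, x):
        self._shape = x.shape
        self._cols = self._im2col(x)
        self._y = _act(self.activation, self._cols @ self.W + self.b)
        return self._y

    def backward(self, g):
        B, L, C = self._shape
        g = g * _act_grad(self.activation, self._y)
        self.gW[...] = np.einsum("blk,blo->ko", self._cols, g)
        self.gb[...] = g.sum(axis=(0, 1))
        gcols = (g @ self.W.T).reshape(B, L, self.k, C)
        p = self.d * (self.k - 1) // 2
        gxp = np.zeros((B, L + 2 * p, C))
        for j in range(self.k):
            gxp[:, j * self.d : j * self.d + L] += gcols[:, :, j]
        return gxp[:, p : p + L]


class GatedConvBlock(Layer):
    """Dilated gated convolution with a residual connection.

    out = x + conv_1x1( tanh(conv_a(x)) * sigmoid(conv_b(x)) ), the building
    block used for spectral decoupling networks.
    """

    def __init__(self, channels, kernel, dilation, rng=None):
        super().__init__()
        self.conv_a = Conv1D(channels, channels, kernel, dilation, "tanh", rng)
        self.conv_b = Conv1D(channels, channels, kernel, dilation, "sigmoid", rng)
        self.proj = Conv1D(channels, channels, 1, 1, None, rng)
        for sub in (self.conv_a, self.conv_b, self.proj):
            self.params += sub.params
            self.grads += sub.grads

    def forward(self, x):
        self._a = self.conv_a.forward(x)
        self._b = self.conv_b.forward(x)
        return x + self.proj.forward(self._a * self._b)

    def backward(self, g):
        gg = self.proj.backward(g)
        ga = self.conv_a.backward(gg * self._b)
        gb = self.conv_b.backward(gg * self._a)
        return g + ga + gb


class DenseConv(Layer):
    """Densely connected convolution: concat(x, relu(conv(x)))."""

    def __init__(self, c_in, growth, kernel, rng=None):
        super().__init__()
        self.conv = Conv1D(c_in, growth, kernel, 1, "relu", rng)
        self.params, self.grads = self.conv.params, self.conv.grads
        self.c_in = c_in

    def forward(self, x):
        return np.concatenate([x, self.conv.forward(x)], axis=-1)

    def backward(self, g):
        gx, gnew = g[..., : self.c_in], g[..., self.c_in :]
        return gx + self.conv.backward(gnew)


class BiRNN(Layer):
    """Bidirectional vanilla tanh recurrence, outputs concatenated."""

    def __init__(self, c_in, units, rng=None):
        super().__init__()
        self.units = units
        self.cells = []
        for _ in range(2):
            Wx = _glorot(rng, (c_in, units), c_in, units)
            Wh = _glorot(rng, (units, units), units, units)
            b = np.zeros(units)
            self.cells.append([Wx, Wh, b])
            self.params += [Wx, Wh, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _run(self, x, cell):
        Wx, Wh, b = cell
        B, L, _ = x.shape
        hs = np.zeros((B, L, self.units))
        h = np.zeros((B, self.units))
        for t in range(L):
            h = np.tanh(x[:, t] @ Wx + h @ Wh + b)
            hs[:, t] = h
        return hs

    def forward(self, x):
        self._x = x
        self._h_f = self._run(x, self.cells[0])
        self._h_b = self._run(x[:, ::-1], self.cells[1])
        return np.concatenate([self._h_f, self._h_b[:, ::-1]], axis=-1)

    def _back(self, x, hs, cell, gh_seq, gparams):
        Wx, Wh, b = cell
        B, L, _ = x.shape
        gx = np.zeros_like(x)
        carry = np.zeros((B, self.units))
        gWx, gWh, gb = gparams
        for t in range(L - 1, -1, -1):
            gh = (gh_seq[:, t] + carry) * (1.0 - hs[:, t] ** 2)
            gx[:, t] = gh @ Wx.T
            gWx += x[:, t].T @ gh
            gb += gh.sum(axis=0)
            if t > 0:
                gWh += hs[:, t - 1].T @ gh
            carry = gh @ Wh.T
        return gx

    def backward(self, g):
        u = self.units
        for gr in self.grads:
            gr[...] = 0.0
        gx_f = self._back(self._x, self._h_f, self.cells[0], g[..., :u], self.grads[0:3])
        gx_b = self._back(
            self._x[:, ::-1], self._h_b, self.cells[1], g[:, ::-1, u:], self.grads[3:6]
        )
        return gx_f + gx_b[:, ::-1]


class AvgPool1D(Layer):
    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x):
        B, L, C = x.shape
        self._shape = x.shape
        return x.reshape(B, L // self.pool, self.pool, C).mean(axis=2)

    def backward(self, g):
        B, L, C = self._shape
        return np.repeat(g, self.pool, axis=1) / self.pool


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(self._in)


class FixedLinear(Layer):
    """A frozen linear map y = x @ M (no trainable parameters)."""

    def __init__(self, matrix):
        super().__init__()
        self.M = np.asarray(matrix, dtype=float)

    def forward(self, x):
        return x @ self.M

    def backward(self, g):
        return g @ self.M.T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self):
        return sum(p.size for p in self.params)

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    """ADAM with the standard parameters (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr, clip_norm=None):
        if clip_norm is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if norm > clip_norm:
                grads = [g * (clip_norm / norm) for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
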