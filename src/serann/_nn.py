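"""Minimal neural-network engine: layers, Glorot init, Adam.

Plain-numpy forward/backward implementations of the handful of layer types
the package needs (dense, 2-D and 1-D convolution, max-pooling, embedding,
dropout).  Sized for the small networks used throughout: correctness and
determinism over raw speed.  All randomness flows through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv2D", "Conv1D", "MaxPool2D", "Flatten", "Embedding",
    "Dropout", "Sequential", "Adam",
    "softmax", "softmax_xent", "glorot_uniform",
]


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _act_forward(h: np.ndarray, act: str | None) -> np.ndarray:
    if act is None or act == "linear":
        return h
    if act == "relu":
        return np.maximum(h, 0.0)
    if act == "tanh":
        return np.tanh(h)
    if act == "sigmoid":
        return 1.0 / (1.0 + np.exp(-h))
    raise ValueError(f"unknown activation {act!r}")


def _act_backward(grad: np.ndarray, out: np.ndarray, act: str | None) -> np.ndarray:
    if act is None or act == "linear":
        return grad
    if act == "relu":
        return grad * (out > 0)
    if act == "tanh":
        return grad * (1.0 - out * out)
    if act == "sigmoid":
        return grad * out * (1.0 - out)
    raise ValueError(f"unknown activation {act!r}")


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, act: str | None,
                 rng: np.random.Generator):
        super().__init__()
        self.act = act
        self.W = glorot_uniform((n_in, n_out), n_in, n_out, rng)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        self._out = _act_forward(x @ self.W + self.b, self.act)
        return self._out

    def backward(self, grad):
        grad = _act_backward(grad, self._out, self.act)
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution on (B, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, act: str | None,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.act = kernel, act
        fan_in, fan_out = kernel * kernel * c_in, kernel * kernel * c_out
        self.W = glorot_uniform((kernel * kernel * c_in, c_out), fan_in, fan_out, rng)
        self.b = np.zeros(c_out)
        self.c_in = c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pads(self, size: int) -> tuple[int, int]:
        total = self.k - 1
        return total // 2, total - total // 2

    def forward(self, x, train=False):
        B, H, Wd, C = x.shape
        pt, pb = self._pads(H)
        pl, pr = self._pads(Wd)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, H, Wd, self.k * self.k * C)
        self._cols, self._shape, self._pads_hw = cols, x.shape, (pt, pb, pl, pr)
        self._out = _act_forward(cols @ self.W + self.b, self.act)
        return self._out

    def backward(self, grad):
        grad = _act_backward(grad, self._out, self.act)
        B, H, Wd, C = self._shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads[0] += cols2.T @ g2
        self.grads[1] += g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(B, H, Wd, self.k, self.k, C)
        pt, pb, pl, pr = self._pads_hw
        dxp = np.zeros((B, H + pt + pb, Wd + pl + pr, C))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + H, dj:dj + Wd, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, pt:pt + H, pl:pl + Wd, :]


class Conv1D(Layer):
    """'same'-padded 1-D convolution with stride, on (B, T, C) tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 act: str | None, rng: np.random.Generator):
        super().__init__()
        self.k, self.s, self.act = kernel, stride, act
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = glorot_uniform((kernel * c_in, c_out), fan_in, fan_out, rng)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_len(self, T: int) -> int:
        return -(-T // self.s)

    def forward(self, x, train=False):
        B, T, C = x.shape
        T_out = self.out_len(T)
        total = max((T_out - 1) * self.s + self.k - T, 0)
        pl, pr = total // 2, total - total // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # win: (B, T_p-k+1, C, k) -> strided starts
        win = win[:, ::self.s][:, :T_out]
        cols = win.transpose(0, 1, 3, 2).reshape(B, T_out, self.k * C)
        self._cols, self._shape, self._pl = cols, x.shape, pl
        self._xp_len = xp.shape[1]
        self._out = _act_forward(cols @ self.W + self.b, self.act)
        return self._out

    def backward(self, grad):
        grad = _act_backward(grad, self._out, self.act)
        B, T, C = self._shape
        T_out = grad.shape[1]
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads[0] += cols2.T @ g2
        self.grads[1] += g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(B, T_out, self.k, C)
        dxp = np.zeros((B, self._xp_len, C))
        for o in range(self.k):
            dxp[:, o:o + (T_out - 1) * self.s + 1:self.s, :] += dcols[:, :, o, :]
        return dxp[:, self._pl:self._pl + T, :]


class MaxPool2D(Layer):
    def __init__(self, size: int):
        super().__init__()
        self.s = size

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        s = self.s
        h2, w2 = H // s, W // s
        xc = x[:, :h2 * s, :w2 * s, :]
        blocks = xc.reshape(B, h2, s, w2, s, C).transpose(0, 1, 3, 5, 2, 4)
        blocks = blocks.reshape(B, h2, w2, C, s * s)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, H, W, C = self._shape
        s = self.s
        h2, w2 = H // s, W // s
        dblocks = np.zeros((B, h2, w2, C, s * s))
        np.put_along_axis(dblocks, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((B, H, W, C))
        dxc = dblocks.reshape(B, h2, w2, C, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx[:, :h2 * s, :w2 * s, :] = dxc.reshape(B, h2 * s, w2 * s, C)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Embedding(Layer):
    def __init__(self, n_tokens: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform((n_tokens, width), n_tokens, width, rng)
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x, train=False):
        self._ids = x
        return self.W[x]

    def backward(self, grad):
        np.add.at(self.grads[0], self._ids, grad)
        return None  # integer inputs have no gradient


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def zero_grad(self):
        for lay in self.layers:
            lay.zero_grad()

    def all_params(self):
        return [(p, g) for lay in self.layers for p, g in zip(lay.params, lay.grads)]


class Adam:
    """Standard Adam over a list of (param, grad) array pairs."""

    def __init__(self, param_grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pg = param_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in param_grads]
        self.v = [np.zeros_like(p) for p, _ in param_grads]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, onehot: np.ndarray,
                 eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Mean cross entropy over rows and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(p + eps)).sum() / n)
    return loss, (p - onehot) / n
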