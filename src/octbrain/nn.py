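"""Minimal CPU neural-network engine (numpy) for the attention ResNet.

Implements exactly the layers the classifier needs — 2D convolution ("same"
padding, stride 1 or 2), batch normalization, ReLU/sigmoid, global average
pooling, a dense head — with hand-written backward passes, a weighted
categorical cross-entropy loss and SGD with momentum and L2 weight decay.

Tensors are NHWC float32. Convolution is computed by im2col + one GEMM per
call. Hot layers keep per-shape scratch buffers alive between steps and use
``out=`` arithmetic: repeated fresh multi-MB allocations (page faults) cost
far more than the GEMMs themselves on a single CPU.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .core import ConfigError, GeometryError

DTYPE = np.float32


# Fused elementwise kernels: on one CPU core the batch-norm / ReLU chains are
# memory-bound, and a single numba pass beats the 3-4 temporaries numpy needs.

@nb.njit(fastmath=True, cache=True)
def _bn_moments(x, out_sum, out_sumsq):
    n, c = x.shape
    for j in range(c):
        out_sum[j] = 0.0
        out_sumsq[j] = 0.0
    for i in range(n):
        for j in range(c):
            v = np.float64(x[i, j])
            out_sum[j] += v
            out_sumsq[j] += v * v


@nb.njit(fastmath=True, cache=True)
def _bn_fwd(x, mean, invstd, gamma, beta, xhat, out):
    n, c = x.shape
    for i in range(n):
        for j in range(c):
            xh = (x[i, j] - mean[j]) * invstd[j]
            xhat[i, j] = xh
            out[i, j] = gamma[j] * xh + beta[j]


@nb.njit(fastmath=True, cache=True)
def _bn_bwd_sums(dy, xhat, sum_dy, sum_dy_xhat):
    n, c = dy.shape
    for j in range(c):
        sum_dy[j] = 0.0
        sum_dy_xhat[j] = 0.0
    for i in range(n):
        for j in range(c):
            sum_dy[j] += dy[i, j]
            sum_dy_xhat[j] += dy[i, j] * xhat[i, j]


@nb.njit(fastmath=True, cache=True)
def _bn_bwd(dy, xhat, g, sum_dy, sum_dy_xhat, m, dx):
    n, c = dy.shape
    for i in range(n):
        for j in range(c):
            dx[i, j] = g[j] * (dy[i, j] - (sum_dy[j] + xhat[i, j] * sum_dy_xhat[j]) / m)


@nb.njit(fastmath=True, cache=True)
def _relu_fwd(x, out, mask):
    for i in range(x.shape[0]):
        v = x[i]
        keep = v > 0.0
        mask[i] = keep
        out[i] = v if keep else 0.0


@nb.njit(fastmath=True, cache=True)
def _relu_bwd(dy, mask, dx):
    for i in range(dy.shape[0]):
        dx[i] = dy[i] if mask[i] else 0.0


class _Scratch:
    """Per-layer reusable buffers keyed by name; reallocated only on shape change."""

    def __init__(self):
        self._bufs: dict = {}

    def get(self, key: str, shape: tuple, dtype=DTYPE) -> np.ndarray:
        b = self._bufs.get(key)
        if b is None or b.shape != shape or b.dtype != dtype:
            b = np.empty(shape, dtype=dtype)
            self._bufs[key] = b
        return b


class Param:
    """A trainable array with its gradient; ``decay`` marks L2-regularized kernels."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Conv2d(Layer):
    """2D convolution, "same" padding, NHWC, optional bias."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = False,
                 name: str = "conv"):
        if stride not in (1, 2):
            raise ConfigError(f"{name}: stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (ksize * ksize * cin))
        self.W = Param(rng.normal(0.0, scale, size=(ksize, ksize, cin, cout)),
                       decay=True, name=f"{name}.W")
        self.b = Param(np.zeros(cout), name=f"{name}.b") if bias else None
        self.ksize, self.stride, self.cin, self.cout = ksize, stride, cin, cout
        self._s = _Scratch()
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.cin:
            raise GeometryError(
                f"{self.W.name}: expected {self.cin} input channels, got {x.shape[-1]}"
            )
        n, h, w, _ = x.shape
        k, s = self.ksize, self.stride
        pt, pb = _same_pad(h, k, s)
        pl, pr = _same_pad(w, k, s)
        ho, wo = -(-h // s), -(-w // s)
        if pt or pb or pl or pr:
            xp = self._s.get("xp", (n, h + pt + pb, w + pl + pr, self.cin))
            xp[...] = 0.0
            xp[:, pt:pt + h, pl:pl + w, :] = x
        else:
            xp = x
        # gather windows into a contiguous (n*ho*wo, k*k*cin) column matrix
        cols = self._s.get("cols", (n, ho, wo, k, k, self.cin))
        if k == 1:
            cols[:, :, :, 0, 0, :] = xp[:, ::s, ::s, :][:, :ho, :wo, :]
        else:
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            cols[...] = win[:, ::s, ::s][:, :ho, :wo].transpose(0, 1, 2, 4, 5, 3)
        cols2 = cols.reshape(-1, k * k * self.cin)
        y = self._s.get("y", (n * ho * wo, self.cout))
        np.matmul(cols2, self.W.value.reshape(-1, self.cout), out=y)
        if self.b is not None:
            y += self.b.value
        self._cache = (cols2, (n, h, w), (pt, pl), (ho, wo), xp.shape)
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols2, (n, h, w), (pt, pl), (ho, wo), xp_shape = self._cache
        k, s = self.ksize, self.stride
        dy2 = np.ascontiguousarray(dy, dtype=DTYPE).reshape(-1, self.cout)
        self.W.grad += (cols2.T @ dy2).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        dxp = self._s.get("dxp", xp_shape)
        dxp[...] = 0.0
        dbuf = self._s.get("dbuf", (n, ho, wo, self.cin))
        dbuf2 = dbuf.reshape(-1, self.cin)
        for i in range(k):
            for j in range(k):
                np.matmul(dy2, self.W.value[i, j].T, out=dbuf2)
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += dbuf
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics (momentum 0.9)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), name=f"{name}.gamma")
        self.beta = Param(np.zeros(c), name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._s = _Scratch()
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c = x.shape[-1]
        x2 = np.ascontiguousarray(x, dtype=DTYPE).reshape(-1, c)
        if training:
            s = np.empty(c, np.float64)
            sq = np.empty(c, np.float64)
            _bn_moments(x2, s, sq)
            m = x2.shape[0]
            mean = s / m
            var = np.maximum(sq / m - mean**2, 0.0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        mean = mean.astype(DTYPE)
        xhat = self._s.get("xhat", x.shape)
        out = self._s.get("out", x.shape)
        _bn_fwd(x2, mean, invstd, self.gamma.value, self.beta.value,
                xhat.reshape(-1, c), out.reshape(-1, c))
        self._cache = (xhat, invstd, training)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, training = self._cache
        c = dy.shape[-1]
        dy2 = np.ascontiguousarray(dy, dtype=DTYPE).reshape(-1, c)
        sum_dy = np.empty(c, DTYPE)
        sum_dy_xhat = np.empty(c, DTYPE)
        _bn_bwd_sums(dy2, xhat.reshape(-1, c), sum_dy, sum_dy_xhat)
        self.gamma.grad += sum_dy_xhat
        self.beta.grad += sum_dy
        g = self.gamma.value * invstd
        dx = self._s.get("dx", dy.shape)
        if not training:
            np.multiply(dy, g, out=dx)
            return dx
        _bn_bwd(dy2, xhat.reshape(-1, c), g, sum_dy, sum_dy_xhat,
                DTYPE(dy2.shape[0]), dx.reshape(-1, c))
        return dx


class ReLU(Layer):
    def __init__(self):
        self._s = _Scratch()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mask = self._s.get("mask", x.shape, dtype=bool)
        out = self._s.get("out", x.shape)
        x2 = np.ascontiguousarray(x, dtype=DTYPE)
        _relu_fwd(x2.reshape(-1), out.reshape(-1), mask.reshape(-1))
        self._mask = mask
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self._s.get("dx", dy.shape)
        dy2 = np.ascontiguousarray(dy, dtype=DTYPE)
        _relu_bwd(dy2.reshape(-1), self._mask.reshape(-1), dx.reshape(-1))
        return dx


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._out = (1.0 / (1.0 + np.exp(np.clip(-x, -60.0, 60.0)))).astype(DTYPE)
        return self._out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self._out * (1.0 - self._out)).astype(DTYPE)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return (np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)).astype(DTYPE)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None,
                 name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / din)
        self.W = Param(rng.normal(0.0, scale, size=(din, dout)), decay=True,
                       name=f"{name}.W")
        self.b = Param(np.zeros(dout), name=f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(DTYPE, copy=False)
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.W.value.T).astype(DTYPE)


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           class_weights: np.ndarray | None = None
                           ) -> tuple[float, np.ndarray]:
    """Mean class-weighted categorical cross-entropy and its logit gradient."""
    n, c = logits.shape
    p = softmax(logits.astype(np.float64))
    w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    wi = w[y]
    loss = float(np.mean(-wi * np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    dlogits = (wi[:, None] * (p - onehot) / n).astype(DTYPE)
    return loss, dlogits


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Param], learning_rate: float, momentum: float = 0.9,
                 l2: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.l2 = learning_rate, momentum, l2
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.l2 > 0 and p.decay:
                g = g + 2.0 * self.l2 * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
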