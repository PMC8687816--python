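"""A small NumPy neural-network engine: the layers, loss and optimizer the
channel-mixing CNN needs, with hand-written backpropagation.

Tensors flow through the layers in channels-last layout (batch, height,
width, feature-maps): convolution then reduces to a handful of large, cheap
matrix products (one per kernel offset, or one im2col product when the
contraction is small), which is what makes CPU training of the identification
network practical. Convolution uses cross-correlation with zero padding and
floor output sizing; weights initialize uniformly in +-1/sqrt(fan_in) from a
seeded generator; dropout is "inverted" (activations scaled at train time so
evaluation needs no rescaling). Forward passes cache what backward needs;
call ``forward(..., train=True)`` before ``backward``.

The elementwise hot spots (ELU, the Adam update) are JIT-compiled with numba
when it is importable and fall back to plain NumPy otherwise; both paths
compute the same expressions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "ChannelMix",
    "Conv2d",
    "ELU",
    "MaxPool2d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "log_softmax",
    "nll_loss",
    "nll_loss_grad",
    "Adam",
]

try:  # optional JIT for the elementwise inner loops
    import math

    import numba

    @numba.vectorize(["float32(float32)", "float64(float64)"], cache=True)
    def _elu_fwd(x):
        return x if x > 0 else math.expm1(x)

    @numba.vectorize(
        ["float32(float32, float32)", "float64(float64, float64)"], cache=True
    )
    def _elu_bwd(g, out):
        # d/dx ELU = 1 for x>0 else exp(x) = out+1 (out>0 iff x>0; out=0 -> 1)
        return g if out > 0 else g * (out + 1.0)

    @numba.njit(cache=True, fastmath=False)
    def _adam_update(p, g, m, v, lr, b1, b2, eps, c1, c2):
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr * (m[i] / c1) / (np.sqrt(v[i] / c2) + eps)

except ImportError:  # pragma: no cover - exercised only without numba

    def _elu_fwd(x):
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))

    def _elu_bwd(g, out):
        return np.where(out > 0, g, g * (out + 1.0))

    def _adam_update(p, g, m, v, lr, b1, b2, eps, c1, c2):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        p -= lr * (m / c1) / (np.sqrt(v / c2) + eps)


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ChannelMix(Layer):
    """Per-time-point linear map on the electrode (width) axis, no bias.

    Realizes the learnable separation matrix W of the blind-source-separation
    view: input (B, P, C, 1) -> output (B, P, S, 1), each time-point's channel
    vector projected into S latent sources by y = W x.
    """

    def __init__(self, n_channels: int, n_sources: int, rng: np.random.Generator, dtype):
        self.W = Param(
            "mix.W", _uniform_fan_in(rng, (n_sources, n_channels), n_channels, dtype)
        )

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != 1:
            raise ValueError("channel mixing expects a single input plane")
        self._x = x if train else None
        return (x[..., 0] @ self.W.value.T)[..., None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g2 = grad[..., 0].reshape(-1, grad.shape[2])
        x2 = self._x[..., 0].reshape(-1, self._x.shape[2])
        self.W.grad += g2.T @ x2
        return (grad[..., 0] @ self.W.value)[..., None]


class Conv2d(Layer):
    """2-D cross-correlation with zero padding, floor sizing, and bias.

    Weights are stored (kh, kw, Cin, Cout). Two equivalent evaluation
    strategies: an im2col product when the contraction Cin*kh*kw is small
    (the 1-plane input convolution), otherwise one matmul per kernel offset
    accumulated in place, which avoids the large patch-matrix copy.
    """

    _IM2COL_MAX_K = 64

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        padding: tuple[int, int],
        rng: np.random.Generator,
        dtype,
        name: str = "conv",
    ):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.W = Param(
            f"{name}.W",
            _uniform_fan_in(rng, (kh, kw, in_channels, out_channels), fan_in, dtype),
        )
        self.b = Param(f"{name}.b", _uniform_fan_in(rng, (out_channels,), fan_in, dtype))
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._use_im2col = fan_in <= self._IM2COL_MAX_K

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _geometry(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        b, h, w, ci = x.shape
        ho, wo = self._geometry(h, w)
        co = self.W.value.shape[-1]
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        self._cols = self._xp = None
        if self._use_im2col:
            win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
            # win: (B, Ho, Wo, Ci, kh, kw); flatten the trailing contraction axes
            cols = np.ascontiguousarray(win).reshape(b * ho * wo, ci * kh * kw)
            wmat = np.ascontiguousarray(self.W.value.transpose(2, 0, 1, 3)).reshape(
                ci * kh * kw, co
            )
            out = (cols @ wmat).reshape(b, ho, wo, co)
            if train:
                self._cols = cols
        else:
            out = np.zeros((b, ho, wo, co), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    out += xp[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] @ \
                        self.W.value[i, j]
            if train:
                self._xp = xp
        if train:
            self._x_shape = x.shape
        out += self.b.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        b, h, w, ci = self._x_shape
        _, ho, wo, co = grad.shape
        g2 = grad.reshape(-1, co)
        self.b.grad += g2.sum(axis=0)
        dxp = np.zeros((b, h + 2 * ph, w + 2 * pw, ci), dtype=grad.dtype)
        if self._use_im2col:
            wmat = np.ascontiguousarray(self.W.value.transpose(2, 0, 1, 3)).reshape(
                ci * kh * kw, co
            )
            dwmat = self._cols.T @ g2
            self.W.grad += dwmat.reshape(ci, kh, kw, co).transpose(1, 2, 0, 3)
            dcols = (g2 @ wmat.T).reshape(b, ho, wo, ci, kh, kw)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += \
                        dcols[:, :, :, :, i, j]
        else:
            for i in range(kh):
                for j in range(kw):
                    sl = (
                        slice(None),
                        slice(i, i + sh * ho, sh),
                        slice(j, j + sw * wo, sw),
                        slice(None),
                    )
                    xs = self._xp[sl].reshape(-1, ci)
                    self.W.grad[i, j] += xs.T @ g2
                    dxp[sl] += grad @ self.W.value[i, j].T
        if ph or pw:
            return np.ascontiguousarray(dxp[:, ph : ph + h, pw : pw + w, :])
        return dxp


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = _elu_fwd(x)
        self._out = out if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return _elu_bwd(grad, self._out)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (stride equals kernel).

    The two kernels the architecture uses, (2,1) and (1,2), halve one axis
    and take a fast two-way maximum; ties go to the earlier element.
    """

    def __init__(self, kernel: tuple[int, int]):
        if kernel not in ((2, 1), (1, 2)):
            raise ValueError("supported pool kernels: (2,1) and (1,2)")
        self.kernel = kernel
        self.axis = 1 if kernel == (2, 1) else 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n = x.shape[self.axis]
        if n % 2:
            raise ValueError(
                f"axis of length {n} not divisible by pool kernel {self.kernel}"
            )
        first = [slice(None)] * 4
        second = [slice(None)] * 4
        first[self.axis] = slice(0, None, 2)
        second[self.axis] = slice(1, None, 2)
        a, bb = x[tuple(first)], x[tuple(second)]
        mask = a >= bb
        out = np.where(mask, a, bb)
        if train:
            self._mask = mask
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.empty(self._in_shape, dtype=grad.dtype)
        first = [slice(None)] * 4
        second = [slice(None)] * 4
        first[self.axis] = slice(0, None, 2)
        second[self.axis] = slice(1, None, 2)
        took_first = grad * self._mask  # winner takes the whole gradient
        dx[tuple(first)] = took_first
        dx[tuple(second)] = grad - took_first
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng, dtype, name="fc"):
        self.W = Param(
            f"{name}.W",
            _uniform_fan_in(rng, (out_features, in_features), in_features, dtype),
        )
        self.b = Param(f"{name}.b", _uniform_fan_in(rng, (out_features,), in_features, dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Dropout(Layer):
    """Inverted dropout: active only in train mode; identity in evaluation."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0


def log_softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise log of the softmax, computed stably."""
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def nll_loss(logp: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy: -mean(log p of the true class)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logp.shape[1]:
        raise ValueError(
            f"labels must lie in [0, {logp.shape[1]}); got "
            f"[{labels.min()}, {labels.max()}]"
        )
    return float(-logp[np.arange(len(labels)), labels].mean())


def nll_loss_grad(logp: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy w.r.t. the pre-softmax scores.

    The log-softmax Jacobian is folded in, giving the usual fused form
    (softmax - onehot) / B — pass the result into the backward pass of the
    layer stack that produced the raw scores.
    """
    b, _ = logp.shape
    grad = np.exp(logp)
    grad[np.arange(b), labels] -= 1.0
    return (grad / b).astype(logp.dtype)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 3e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.beta1**self.t
        c2 = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            _adam_update(
                p.value.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                p.value.dtype.type(self.lr),
                p.value.dtype.type(self.beta1),
                p.value.dtype.type(self.beta2),
                p.value.dtype.type(self.eps),
                p.value.dtype.type(c1),
                p.value.dtype.type(c2),
            )
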