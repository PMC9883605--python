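"""Minimal NumPy neural-network engine for 1D signal classification.

Implements exactly the layers the residual classifier needs — 1D
convolution (im2col + BLAS matmul), batch normalization, ReLU, inverted
dropout, max/global-mean pooling, a dense head — each with a hand-written
backward pass, plus Adam and a numerically stable binary cross-entropy on
logits. Everything is float32 and single-threaded-CPU friendly.

Conventions: activations are (batch, channels, length); a layer's
``forward`` caches what ``backward`` needs; ``backward`` accumulates
parameter gradients in place and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "RngBox",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]

DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient d loss / d z."""
    z = z.astype(np.float64)
    # softplus(z) - y*z, computed stably via max(z,0) - y*z + log1p(exp(-|z|))
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(DTYPE)
    return loss, grad


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class RngBox:
    """Shared mutable RNG handle so a model can be reseeded in one place."""

    def __init__(self, seed: int = 0):
        self.gen = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.gen = np.random.default_rng(seed)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_length(self, L: int) -> int:
        return L


class Conv1d(Layer):
    """1D convolution, He-initialised, 'same'-style padding of kernel//2."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.weight = Parameter(rng.normal(0, std, (out_ch, in_ch * kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def out_length(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, L = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        W = self.out_length(L)
        if W < 1:
            raise ValueError(f"input length {L} too short for kernel {k} stride {s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = np.empty((N, C, k, W), dtype=DTYPE)
        for j in range(k):
            cols[:, :, j, :] = xp[:, :, j : j + s * W : s]
        cols2 = cols.reshape(N, C * k, W)
        y = np.matmul(self.weight.value, cols2) + self.bias.value[:, None]
        self._cache = (cols2, x.shape)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols2, xshape = self._cache
        N, C, L = xshape
        k, s, p = self.kernel, self.stride, self.pad
        W = grad.shape[2]
        self.bias.grad += grad.sum(axis=(0, 2))
        F = grad.shape[1]
        A = np.ascontiguousarray(grad.transpose(1, 0, 2)).reshape(F, -1)
        B = np.ascontiguousarray(cols2.transpose(1, 0, 2)).reshape(cols2.shape[1], -1)
        self.weight.grad += A @ B.T
        dcols2 = np.matmul(self.weight.value.T, grad)  # (N, C*k, W)
        dcols = dcols2.reshape(N, C, k, W)
        dxp = np.zeros((N, C, L + 2 * p), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j : j + s * W : s] += dcols[:, :, j, :]
        return dxp[:, :, p : p + L] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, L = x.shape
        m = N * L
        if training:
            mean = x.mean(axis=(0, 2))
            # single-pass variance via a BLAS-backed sum of squares
            sumsq = np.einsum("ncl,ncl->c", x, x, optimize=True)
            var = np.maximum(sumsq / m - mean * mean, 0.0)
            mom = self.momentum
            self.running_mean = (mom * self.running_mean + (1 - mom) * mean).astype(DTYPE)
            self.running_var = (mom * self.running_var + (1 - mom) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        # fused affine: y = x * (gamma*ivar) + (beta - mean*gamma*ivar)
        scale = self.gamma.value * ivar
        shift = self.beta.value - mean * scale
        y = x * scale[None, :, None]
        y += shift[None, :, None].astype(DTYPE)
        self._cache = (x, mean.astype(DTYPE), ivar) if training else None
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, mean, ivar = self._cache
        N, C, L = grad.shape
        m = N * L
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self.gamma.grad += np.einsum("ncl,ncl->c", grad, xhat, optimize=True)
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2))
        s2 = np.einsum("ncl,ncl->c", dxhat, xhat, optimize=True)
        # dx = ivar/m * (m*dxhat - s1 - xhat*s2), built in place
        xhat *= s2[None, :, None]
        dxhat *= m
        dxhat -= s1[None, :, None]
        dxhat -= xhat
        dxhat *= (ivar / m)[None, :, None]
        return dxhat


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        # in place: x is always a fresh intermediate (conv/BN/residual sum)
        np.maximum(x, 0, out=x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad *= self._mask
        return grad


class Dropout(Layer):
    """Inverted dropout; a no-op outside training mode."""

    def __init__(self, rate: float, rng_box: RngBox):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng_box = rng_box
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng_box.gen.random(x.shape, dtype=np.float32) < keep
        ).astype(DTYPE) / DTYPE(keep)
        x *= self._mask  # in place: input is the preceding ReLU's output
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        grad *= self._mask
        return grad


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel == stride); odd tail is dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def out_length(self, L: int) -> int:
        return L // self.kernel

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, L = x.shape
        k = self.kernel
        W = L // k
        if k == 2:
            x0, x1 = x[:, :, : 2 * W : 2], x[:, :, 1 : 2 * W : 2]
            mask = x0 >= x1  # ties go to the first element, like argmax
            self._cache = (mask, x.shape)
            return np.where(mask, x0, x1)
        xv = x[:, :, : W * k].reshape(N, C, W, k)
        idx = xv.argmax(axis=3)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cached, xshape = self._cache
        N, C, L = xshape
        k = self.kernel
        W = L // k
        dx = np.zeros((N, C, L), dtype=grad.dtype)
        if k == 2:
            mask = cached
            dx[:, :, : 2 * W : 2] = grad * mask
            dx[:, :, 1 : 2 * W : 2] = grad * ~mask
            return dx
        idx = cached
        dxv = np.zeros((N, C, W, k), dtype=grad.dtype)
        np.put_along_axis(dxv, idx[..., None], grad[..., None], axis=3)
        dx[:, :, : W * k] = dxv.reshape(N, C, W * k)
        return dx


class GlobalAvgPool1d(Layer):
    """(N, C, L) -> (N, C) mean over the length axis."""

    def out_length(self, L: int) -> int:
        return 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._L, axis=2) / DTYPE(self._L)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def out_length(self, L: int) -> int:
        for layer in self.layers:
            L = layer.out_length(L)
        return L

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with a mutable learning rate (for plateau scheduling)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
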