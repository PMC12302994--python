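"""Minimal numpy implementation of a 1-D convolutional classifier.

The architecture is small and fixed (three strided conv blocks with group
normalization, three fully connected layers with batch normalization), so
a dependency-free forward/backward implementation is practical: every
layer is a dataclass-free object with ``forward(x, train)`` and
``backward(grad)`` methods, parameters are updated with Adam, and all
randomness flows through a caller-supplied ``numpy.random.Generator`` so
training is bit-deterministic given a seed.

Convolutions are *valid* (unpadded): output length floor((L - k)/s) + 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "GroupNorm",
    "BatchNorm",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_grad",
    "conv_output_length",
]


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid (unpadded) strided convolution output length."""
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean multiclass cross-entropy and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Valid 1-D convolution, implemented as an im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.kernel, self.stride = kernel, stride
        fan_in = in_ch * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _patches(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, L) -> (N, L_out, C * kernel)
        n, c, length = x.shape
        l_out = conv_output_length(length, self.kernel, self.stride)
        idx = (np.arange(l_out)[:, None] * self.stride) + np.arange(self.kernel)
        return x[:, :, idx].transpose(0, 2, 1, 3).reshape(n, l_out, c * self.kernel)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        self._p = self._patches(x)  # (N, L_out, C*k)
        w = self.W.reshape(self.W.shape[0], -1)  # (out, C*k)
        out = self._p @ w.T + self.b  # (N, L_out, out)
        return out.transpose(0, 2, 1)  # (N, out, L_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 1)  # (N, L_out, out)
        self.db[:] = g.sum(axis=(0, 1))
        self.dW[:] = np.einsum("nlo,nlp->op", g, self._p).reshape(self.W.shape)
        w = self.W.reshape(self.W.shape[0], -1)
        gp = g @ w  # (N, L_out, C*k)
        n, c, length = self._x.shape
        l_out = gp.shape[1]
        gx = np.zeros_like(self._x)
        gp = gp.reshape(n, l_out, c, self.kernel).transpose(0, 2, 1, 3)
        idx = (np.arange(l_out)[:, None] * self.stride) + np.arange(self.kernel)
        np.add.at(gx, (slice(None), slice(None), idx), gp)
        return gx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _Norm(Layer):
    """Shared affine machinery for group/batch normalization."""

    def __init__(self, channels: int) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class GroupNorm(_Norm):
    """Per-sample normalization over channel groups x length (eps 1e-5)."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5) -> None:
        super().__init__(channels)
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups, self.eps = groups, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, length = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * length)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) * self._inv).reshape(n, c, length)
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = grad.shape
        g = self.groups
        self.dgamma[:] = (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta[:] = grad.sum(axis=(0, 2))
        dxhat = (grad * self.gamma[None, :, None]).reshape(n, g, c // g * length)
        xhat = self._xhat.reshape(n, g, c // g * length)
        m = dxhat.shape[2]
        dx = (
            self._inv
            * (dxhat - dxhat.mean(axis=2, keepdims=True)
               - xhat * (dxhat * xhat).mean(axis=2, keepdims=True))
        )
        return dx.reshape(n, c, length)


class BatchNorm(_Norm):
    """Batch normalization over the batch axis of (N, F) activations."""

    def __init__(self, features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__(features)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(features)
        self.running_var = np.ones(features)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.dgamma[:] = (grad * self._xhat).sum(axis=0)
        self.dbeta[:] = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return self._inv * (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.b = np.zeros(out_f)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
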