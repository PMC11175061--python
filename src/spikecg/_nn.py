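"""Minimal dense/convolutional layer kit with hand-written gradients.

The networks in this package are small (a few hundred thousand parameters)
and are trained on one CPU, so the layers are plain numpy with explicit
``forward``/``backward`` methods and cached activations.  All randomness is
routed through an explicit ``numpy.random.Generator`` so training runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Linear",
    "Conv1d",
    "AvgPool1d",
    "ReLU",
    "LeakyReLU",
    "Flatten",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Linear(Layer):
    """Affine map x @ W.T + b for inputs of shape (N, in_features)."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        init_scale: float | None = None,
    ) -> None:
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / in_features)
        self.W = Param(rng.normal(0.0, scale, size=(out_features, in_features)), "W")
        self.b = Param(np.zeros(out_features), "b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value

    # stateless wrt time: usable repeatedly inside the spiking loop
    def forward_nocache(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.value.T + self.b.value

    def backward_from(self, grad: np.ndarray, x: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with 'same' zero padding.

    Input (N, C_in, L) -> output (N, C_out, L).  Kernels must have odd size.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ) -> None:
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.kernel_size = kernel_size
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = Param(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)), "W"
        )
        self.b = Param(np.zeros(out_channels), "b")
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        if length < self.kernel_size:
            raise ValueError(
                f"input length {length} shorter than receptive field "
                f"{self.kernel_size}"
            )
        self._xp = xp
        out = np.zeros((n, self.W.value.shape[0], length))
        for k in range(self.kernel_size):
            # (N, C_in, L) x (C_out, C_in) summed over C_in
            out += np.einsum(
                "ncl,oc->nol", xp[:, :, k : k + length], self.W.value[:, :, k]
            )
        return out + self.b.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xp is not None
        xp = self._xp
        n, c_out, length = grad.shape
        pad = self.kernel_size // 2
        dxp = np.zeros_like(xp)
        for k in range(self.kernel_size):
            self.W.grad[:, :, k] += np.einsum(
                "nol,ncl->oc", grad, xp[:, :, k : k + length]
            )
            dxp[:, :, k : k + length] += np.einsum(
                "nol,oc->ncl", grad, self.W.value[:, :, k]
            )
        self.b.grad += grad.sum(axis=(0, 2))
        return dxp[:, :, pad : pad + length] if pad else dxp


class AvgPool1d(Layer):
    """Non-overlapping average pooling along the last axis (valid mode)."""

    def __init__(self, pool_size: int) -> None:
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool_size = pool_size
        self._in_length = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool_size
        self._in_length = x.shape[-1]
        if p == 1:
            return x
        l_out = x.shape[-1] // p
        trimmed = x[..., : l_out * p]
        return trimmed.reshape(*x.shape[:-1], l_out, p).mean(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.pool_size
        if p == 1:
            return grad
        expanded = np.repeat(grad, p, axis=-1) / p
        out = np.zeros((*grad.shape[:-1], self._in_length))
        out[..., : expanded.shape[-1]] = expanded
        return out


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        self.negative_slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.negative_slope * grad)


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
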