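"""Minimal CPU neural-network engine used by the inverse regressors.

Implements exactly what the two regression architectures need — dilated
causal 1-D convolutions, strided 2-D convolutions, ReLU, global average
pooling, a linear head — with hand-written backward passes, an Adam
optimizer and a one-cycle learning-rate schedule.  Everything is plain
numpy, deterministic given the seed of the generator used for
initialization and batching.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Linear", "ReLU", "CausalConv1d", "Conv2d",
    "GlobalAvgPool1d", "GlobalAvgPool2d", "Sequential", "Adam",
    "one_cycle_lr", "mse_loss",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class CausalConv1d(Layer):
    """Dilated causal convolution on (B, C, L); output length equals input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng: np.random.Generator):
        fan_in = c_in * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.dilation = dilation

    def params(self):
        return [self.w, self.b]

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel - 1) * self.dilation

    def forward(self, x):
        pad = (self.kernel - 1) * self.dilation
        xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
        self._xp = xp
        L = x.shape[2]
        out = np.empty((x.shape[0], self.w.value.shape[0], L))
        out[:] = self.b.value[None, :, None]
        for i in range(self.kernel):
            o = i * self.dilation
            out += np.einsum("oc,bcl->bol", self.w.value[:, :, i], xp[:, :, o : o + L], optimize=True)
        return out

    def backward(self, grad):
        xp = self._xp
        pad = (self.kernel - 1) * self.dilation
        L = grad.shape[2]
        dxp = np.zeros_like(xp)
        for i in range(self.kernel):
            o = i * self.dilation
            self.w.grad[:, :, i] += np.einsum("bol,bcl->oc", grad, xp[:, :, o : o + L], optimize=True)
            dxp[:, :, o : o + L] += np.einsum("oc,bol->bcl", self.w.value[:, :, i], grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        return dxp[:, :, pad:]


class Conv2d(Layer):
    """Strided 2-D convolution on (B, C, H, W) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, padding: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        H = (xp.shape[2] - k) // s + 1
        W = (xp.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._win = win  # (B, C, H, W, k, k)
        out = np.einsum("bchwij,ocij->bohw", win, self.w.value, optimize=True)
        out += self.b.value[None, :, None, None]
        self._out_shape = (H, W)
        return out

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.padding
        H, W = self._out_shape
        self.w.grad += np.einsum("bohw,bchwij->ocij", grad, self._win, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * H : s, j : j + s * W : s] += np.einsum(
                    "oc,bohw->bchw", self.w.value[:, :, i, j], grad, optimize=True
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool1d(Layer):
    def forward(self, x):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class GlobalAvgPool2d(Layer):
    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad[:, :, None, None], grad.shape + (h, w)).copy() / (h * w)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state length does not match model parameters")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = a


class Adam:
    def __init__(self, params: list[Param], betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def one_cycle_lr(step: int, total_steps: int, lr_max: float, pct_start: float = 0.25,
                 div_start: float = 25.0, div_final: float = 1e4) -> float:
    """One-cycle schedule: cosine warm-up then cosine annealing.

    Rises from ``lr_max / div_start`` to ``lr_max`` over the first
    ``pct_start`` fraction of steps, then decays to ``lr_max / div_final``.
    """
    if total_steps <= 1:
        return lr_max
    warm = max(1, int(round(pct_start * total_steps)))
    if step < warm:
        frac = step / warm
        lo = lr_max / div_start
        return lo + (lr_max - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - warm) / max(1, total_steps - warm)
    lo = lr_max / div_final
    return lo + (lr_max - lo) * 0.5 * (1 + np.cos(np.pi * frac))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to the prediction."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
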