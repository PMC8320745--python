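"""Neural-network building blocks on top of the autodiff core.

Convolutions are 3x3, stride 1, "same" padding, implemented with
``sliding_window_view`` + ``einsum``; spatial downsampling is done by 2x2
average pooling.  Weight initialization is He-style fan-in scaling drawn from
a caller-supplied :class:`numpy.random.Generator`, so a model built twice from
the same seed has identical parameters.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor


class Module:
    """Base class: parameter discovery + train/eval mode flag."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Dense layer; ``gain`` rescales the He fan-in init (use < 1 for layers
    feeding saturating activations, so units start inside their active band)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias_init: float = 0.0, gain: float = 1.0):
        scale = gain * np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.full(n_out, bias_init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3 same-padding convolution on (N, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3):
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, ksize, ksize)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.ksize = ksize
        self.pad = ksize // 2

    def __call__(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, p = self.ksize, self.pad
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        out_data = np.einsum("nchwij,fcij->nfhw", win, w.data, optimize=True) + b.data[:, None, None]

        def backward(g):
            if w.requires_grad:
                w._accum(np.einsum("nchwij,nfhw->fcij", win, g, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
                gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
                w_flip = w.data[:, :, ::-1, ::-1]
                x._accum(np.einsum("nfhwij,fcij->nchw", gwin, w_flip, optimize=True))

        return Tensor._make(out_data, (x, w, b), backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {h}x{w}")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.shape

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None], x.shape) / (h * w))

    return Tensor._make(x.data.mean(axis=(2, 3)), (x,), backward)


def log_softmax(z: Tensor) -> Tensor:
    """Row-wise log-softmax via the max-shift trick (max treated as constant)."""
    shift = z - z.data.max(axis=1, keepdims=True)
    return shift - shift.exp().sum(axis=1, keepdims=True).log()
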