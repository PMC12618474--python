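"""Minimal 3D neural-network layers with explicit forward/backward passes.

No autodiff framework is involved: each layer caches what its backward pass
needs and returns the gradient with respect to its input, accumulating
parameter gradients in :class:`Param` objects.  All operations are plain
NumPy (sliding-window views + tensordot for convolutions), which keeps the
stack fully deterministic for a fixed seed and fast enough for the
desk-scale grids this package targets.

Tensor layout throughout: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "Upsample3d",
    "Adam",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding, odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True, name: str = "conv"):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel_size**3
        # He initialization, appropriate for the ReLU blocks this feeds
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, *(kernel_size,) * 3))
        self.weight = Param(w.astype(np.float32), f"{name}.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32),
                          f"{name}.bias") if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    @staticmethod
    def _windows(x: np.ndarray, k: int) -> np.ndarray:
        """Padded sliding windows, shape (N, C, D, H, W, k, k, k)."""
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        return sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel_size
        win = self._windows(x, k)
        # (N,C,D,H,W,k,k,k) x (Co,C,k,k,k) -> (N,D,H,W,Co)
        y = np.tensordot(win, self.weight.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        y = np.ascontiguousarray(np.moveaxis(y, -1, 1))
        if self.bias is not None:
            y += self.bias.data[None, :, None, None, None]
        if train:
            self._cache = win
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        win = self._cache
        k = self.kernel_size
        g = np.moveaxis(grad_out, 1, -1)  # (N,D,H,W,Co)
        self.weight.grad += np.tensordot(
            g, win, axes=([0, 1, 2, 3], [0, 2, 3, 4])
        )  # (Co, C, k, k, k)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3, 4))
        # grad wrt input: correlate grad_out with spatially flipped kernels
        gwin = self._windows(grad_out, k)  # (N,Co,D,H,W,k,k,k)
        w_flip = self.weight.data[:, :, ::-1, ::-1, ::-1]
        gx = np.tensordot(gwin, w_flip, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
        self._cache = None
        return np.ascontiguousarray(np.moveaxis(gx, -1, 1))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(inv_std)
        if train:
            self._cache = (xhat, inv_std)
        return self._bc(self.gamma.data) * xhat + self._bc(self.beta.data)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = grad_out.size // grad_out.shape[1]
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        gxhat = grad_out * self._bc(self.gamma.data)
        # standard batch-norm backward in terms of xhat
        gx = (gxhat
              - self._bc(gxhat.mean(axis=axes))
              - xhat * self._bc((gxhat * xhat).mean(axis=axes)))
        self._cache = None
        return gx * self._bc(inv_std)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out * self._mask
        self._mask = None
        return g


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out * self._y * (1.0 - self._y)
        self._y = None
        return g


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (dims must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        xw = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xw = xw.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            N, C, D // 2, H // 2, W // 2, 8)
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        N, C, D, H, W = shape
        gw = np.zeros((N, C, D // 2, H // 2, W // 2, 8), dtype=grad_out.dtype)
        np.put_along_axis(gw, idx[..., None], grad_out[..., None], axis=-1)
        gw = gw.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
        gx = gw.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, D, H, W)
        self._cache = None
        return gx


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix for 2x upsampling (half-pixel centers)."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[i, lo_c] += 1.0 - frac
        M[i, hi_c] += frac
    return M


class Upsample3d(Layer):
    """Trilinear 2x upsampling, implemented as separable linear maps."""

    def __init__(self):
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(2 * n_in, n_in)
        return self._mats[n_in]

    @staticmethod
    def _apply_axis(x: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
        y = np.tensordot(x, M, axes=([axis], [1]))  # result axis goes last
        return np.moveaxis(y, -1, axis)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        y = x
        for axis in (2, 3, 4):
            y = self._apply_axis(y, self._mat(x.shape[axis]), axis)
        return np.ascontiguousarray(y)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out
        for axis in (2, 3, 4):
            g = self._apply_axis(g, self._mat(self._in_shape[axis]).T, axis)
        self._in_shape = None
        return np.ascontiguousarray(g)


class Adam:
    """Adaptive-moment optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
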