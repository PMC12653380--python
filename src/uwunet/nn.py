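"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the primitives the segmentation networks need —
3x3/1x1/strided convolutions (im2col + GEMM), 2x2 transposed convolution,
batch normalization, ReLU/LeakyReLU, 2x2 max pooling — plus the Adam
optimizer.  Everything is float32 and fully deterministic given a seeded
``numpy.random.Generator``: there is no threading or stochastic kernel
selection, so repeated runs on the same machine are bit-identical.

Each layer caches what its backward pass needs during ``forward``; calling
``backward`` consumes the cache.  Gradients accumulate into
``Parameter.grad`` and are cleared by ``zero_grad``.

Layers operate on channel-major batches of shape (C, N, H, W): keeping the
channel-patch axis contiguous with the GEMM output lets the convolution
forward and backward passes avoid large transpose copies, which dominate
the runtime otherwise.  The models in :mod:`uwunet.architectures` convert
from the conventional (N, C, H, W) at their public boundary.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

#: Working precision. float32 throughout for speed; tests flip this to
#: float64 for tight finite-difference gradient checks.
DTYPE = np.float32

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "MaxPool2x2",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: subclasses define forward/backward and list parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        return [(f"{prefix}{i}", p) for i, p in enumerate(self.parameters())]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold k×k patches of ``x`` (C,N,H,W) into a (C·k·k, N·Ho·Wo) matrix.

    The patch axis is kept major and the spatial axis innermost so the
    gather copy streams through memory in long contiguous runs.
    """
    c, n, h, w = x.shape
    if pad:
        xp = np.zeros((c, n, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
        xp[:, :, pad:pad + h, pad:pad + w] = x
        x = xp
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = as_strided(
        x,
        shape=(c, k, k, n, ho, wo),
        strides=(s0, s2, s3, s1, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(c * k * k, n * ho * wo)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    """Scatter-add patch gradients back to the input layout (adjoint of _im2col)."""
    c, n, h, w = x_shape
    dx = np.zeros((c, n, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(c, k, k, n, ho, wo)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += d6[:, i, j]
    if pad:
        dx = np.ascontiguousarray(dx[:, :, pad:pad + h, pad:pad + w])
    return dx


class Conv2d(Module):
    """2-D convolution with bias, He-normal initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad = stride, pad
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        cols, ho, wo = _im2col(x, self.kernel, self.stride, self.pad)
        wr = self.weight.data.reshape(self.out_ch, -1)
        n = x.shape[1]
        out = wr @ cols                      # (cout, N*Ho*Wo)
        out += self.bias.data[:, None]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(self.out_ch, n, ho, wo)

    def backward(self, grad_out):
        cols, x_shape, ho, wo = self._cache
        self._cache = None
        g = np.ascontiguousarray(grad_out).reshape(self.out_ch, -1)
        self.weight.grad += (g @ cols.T).reshape(self.weight.data.shape)
        self.bias.grad += g.sum(axis=1)
        dcols = self.weight.data.reshape(self.out_ch, -1).T @ g
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad, ho, wo)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution: doubles H and W.

    Windows do not overlap at stride 2, so the forward pass is a single
    tensor contraction followed by a pixel-shuffle style reshape.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Parameter(rng.normal(0.0, std, (in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        c, n, h, w = x.shape
        # (Co,2,2,N,H,W) -> (Co,N,H,2,W,2) -> (Co,N,2H,2W)
        y = np.tensordot(self.weight.data, x, axes=([0], [0]))
        y = np.ascontiguousarray(y.transpose(0, 3, 4, 1, 5, 2))
        y = y.reshape(self.out_ch, n, 2 * h, 2 * w)
        y += self.bias.data[:, None, None, None]
        self._cache = (x, (c, n, h, w))
        return y

    def backward(self, grad_out):
        x, (c, n, h, w) = self._cache
        self._cache = None
        gy = grad_out.reshape(self.out_ch, n, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        # gy: (Co,N,H,W,2,2)
        self.weight.grad += np.tensordot(x, gy, axes=([1, 2, 3], [1, 2, 3]))
        self.bias.grad += grad_out.sum(axis=(1, 2, 3))
        return np.tensordot(self.weight.data, gy, axes=([1, 2, 3], [0, 4, 5]))


class BatchNorm2d(Module):
    """Per-channel batch normalization with learned scale and shift.

    Training mode normalizes with batch statistics and updates running
    estimates (momentum 0.1); evaluation mode uses the running estimates.
    """

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=DTYPE)
        self.running_var = np.ones(num_ch, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) * inv_std[:, None, None, None]
        self._cache = (xhat.astype(x.dtype), inv_std.astype(x.dtype), train)
        return (self.gamma.data[:, None, None, None] * xhat
                + self.beta.data[:, None, None, None])

    def backward(self, grad_out):
        xhat, inv_std, train = self._cache
        self._cache = None
        axes = (1, 2, 3)
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        scale = (self.gamma.data * inv_std)[:, None, None, None]
        if not train:
            return grad_out * scale
        m = grad_out.shape[1] * grad_out.shape[2] * grad_out.shape[3]
        mean_g = grad_out.mean(axis=axes)[:, None, None, None]
        mean_gx = (grad_out * xhat).sum(axis=axes)[:, None, None, None] / m
        return scale * (grad_out - mean_g - xhat * mean_gx)


class ReLU(Module):
    def forward(self, x, train=False):
        mask = x > 0
        self._mask = mask
        return x * mask

    def backward(self, grad_out):
        mask = self._mask
        self._mask = None
        return grad_out * mask


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope

    def forward(self, x, train=False):
        mask = x > 0
        self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad_out):
        mask = self._mask
        self._mask = None
        return np.where(mask, grad_out, self.slope * grad_out)


class MaxPool2x2(Module):
    """2x2 max pooling, stride 2.  Ties route the gradient to the first
    maximal element (deterministic)."""

    def forward(self, x, train=False):
        c, n, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool input must have even H,W; got {h}x{w}")
        view = x.reshape(c, n, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        view = np.ascontiguousarray(view).reshape(c, n, h // 2, w // 2, 4)
        idx = view.argmax(axis=-1)
        out = np.take_along_axis(view, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (c, n, h, w))
        return out

    def backward(self, grad_out):
        idx, (c, n, h, w) = self._cache
        self._cache = None
        dview = np.zeros((c, n, h // 2, w // 2, 4), dtype=grad_out.dtype)
        np.put_along_axis(dview, idx[..., None], grad_out[..., None], axis=-1)
        dx = dview.reshape(c, n, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(c, n, h, w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class Adam:
    """Adam optimizer with bias-corrected first/second moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
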