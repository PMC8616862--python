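"""Minimal NumPy building blocks for 3D convolutional networks.

Volumetric activations are stored channels-first as ``(N, C, X, Y, Z)``
``float32`` arrays.  Convolutions are evaluated as im2col patch matrices
multiplied through BLAS; every layer implements an explicit ``backward``
so full networks (including an encoder--decoder U-Net with skip
connections) can be trained end-to-end with Adam on a single CPU.

Only the operations the weight-estimation pipeline needs are provided:
3D convolution, transposed convolution (kernel 2, stride 2), 2x2x2 max
pooling with floor semantics, batch normalization, ReLU / sigmoid,
dropout, fully connected layers, and the two losses (voxel-wise binary
cross-entropy and mean squared error).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "ce_loss",
    "bce_with_logits",
    "mse_loss",
]

# Keep per-chunk im2col buffers below ~192 MiB so peak memory stays small
# even for the full-resolution U-Net.
_MAX_COL_BYTES = 192 * 1024**2


class Parameter:
    """A trainable array together with its current gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: children are discovered by attribute inspection."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def set_rng(self, rng: np.random.Generator) -> None:
        """Hand a random stream to stochastic layers (dropout)."""
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays that define the module's state (for checkpoints)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm3d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    """3D convolution with cubic kernel, isotropic stride and padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * k**3
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        self._x_shape: tuple[int, ...] | None = None
        self._xp: np.ndarray | None = None

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return tuple((dim + 2 * p - k) // s + 1 for dim in spatial)  # type: ignore[return-value]

    def _offsets(self):
        k = self.kernel_size
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def _view(self, xp: np.ndarray, off: tuple[int, int, int], out_sp: tuple[int, int, int]) -> np.ndarray:
        s = self.stride
        i, j, l = off
        ox, oy, oz = out_sp
        return xp[:, :, i : i + s * ox : s, j : j + s * oy : s, l : l + s * oz : s]

    def _w_mat(self) -> np.ndarray:
        # (Cout, k^3 * Cin) with rows ordered (offset, channel)
        return np.ascontiguousarray(
            self.weight.data.transpose(0, 2, 3, 4, 1).reshape(self.out_channels, -1)
        )

    def _cols(self, xp: np.ndarray, out_sp: tuple[int, int, int]) -> np.ndarray:
        """Patch matrix (k^3 * Cin, N * ox * oy * oz), assembled with one
        near-contiguous slice copy per kernel offset."""
        n = xp.shape[0]
        c = self.in_channels
        rows = len(self._offsets())
        cols = np.empty((rows, c, n, *out_sp), dtype=np.float32)
        for r, off in enumerate(self._offsets()):
            view = self._view(xp, off, out_sp)  # (n, c, ox, oy, oz)
            np.copyto(cols[r], view.transpose(1, 0, 2, 3, 4))
        return cols.reshape(rows * c, -1)

    def _chunk(self, out_sp: tuple[int, int, int]) -> int:
        per_sample = self.in_channels * self.kernel_size**3 * int(np.prod(out_sp)) * 4
        return max(1, _MAX_COL_BYTES // max(per_sample, 1))

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._x_shape = x.shape
        self._xp = xp
        n = x.shape[0]
        out_sp = self._out_shape(x.shape[2:])
        w = self._w_mat()
        out = np.empty((n, self.out_channels, *out_sp), dtype=np.float32)
        step = self._chunk(out_sp)
        for i in range(0, n, step):
            sl = slice(i, min(i + step, n))
            y = w @ self._cols(xp[sl], out_sp)  # (Cout, chunk * spatial)
            out[sl] = y.reshape(self.out_channels, sl.stop - sl.start, *out_sp).transpose(1, 0, 2, 3, 4)
        out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._xp is not None and self._x_shape is not None
        xp, (n, c, *_) = self._xp, self._x_shape
        k, p = self.kernel_size, self.padding
        out_sp = dout.shape[2:]
        w = self._w_mat()
        dw2 = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        step = self._chunk(out_sp)
        for i in range(0, n, step):
            sl = slice(i, min(i + step, n))
            nn_ = sl.stop - sl.start
            dout2 = np.ascontiguousarray(dout[sl].transpose(1, 0, 2, 3, 4)).reshape(self.out_channels, -1)
            cols = self._cols(xp[sl], out_sp)
            dw2 += dout2 @ cols.T  # (Cout, k^3 * Cin)
            del cols
            dcols = (w.T @ dout2).reshape(k**3, c, nn_, *out_sp).transpose(0, 2, 1, 3, 4, 5)
            dxp_sl = dxp[sl]
            for r, off in enumerate(self._offsets()):
                self._view(dxp_sl, off, out_sp)[...] += dcols[r]
        self.weight.grad = np.ascontiguousarray(
            dw2.reshape(self.out_channels, k, k, k, c).transpose(0, 4, 1, 2, 3)
        )
        self.bias.grad = dout.sum(axis=(0, 2, 3, 4))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ConvTranspose3d(Module):
    """Transposed convolution with kernel 2 and stride 2 (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels, 2, 2, 2), in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, sx, sy, sz = x.shape
        out = np.einsum("ncxyz,coijk->noxiyjzk", x, self.weight.data, optimize=True)
        out = out.reshape(n, self.out_channels, 2 * sx, 2 * sy, 2 * sz)
        out += self.bias.data[None, :, None, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x = self._x
        n, c, sx, sy, sz = x.shape
        blocks = dout.reshape(n, self.out_channels, sx, 2, sy, 2, sz, 2)
        self.weight.grad = np.einsum("ncxyz,noxiyjzk->coijk", x, blocks, optimize=True).astype(np.float32)
        self.bias.grad = dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("noxiyjzk,coijk->ncxyz", blocks, self.weight.data, optimize=True)
        self._x = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class MaxPool3d(Module):
    """2x2x2 max pooling with floor semantics for odd extents."""

    def __init__(self) -> None:
        self._x_shape: tuple[int, ...] | None = None
        self._argmax: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, sx, sy, sz = x.shape
        ox, oy, oz = sx // 2, sy // 2, sz // 2
        self._x_shape = x.shape
        xc = x[:, :, : 2 * ox, : 2 * oy, : 2 * oz]
        win = xc.reshape(n, c, ox, 2, oy, 2, oz, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, ox, oy, oz, 8)
        self._argmax = win.argmax(axis=-1)
        return np.ascontiguousarray(win.max(axis=-1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x_shape is not None and self._argmax is not None
        n, c, sx, sy, sz = self._x_shape
        ox, oy, oz = dout.shape[2:]
        flat = np.zeros((n, c, ox, oy, oz, 8), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = flat.reshape(n, c, ox, oy, oz, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dxc = dxc.reshape(n, c, 2 * ox, 2 * oy, 2 * oz)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, :, : 2 * ox, : 2 * oy, : 2 * oz] = dxc
        self._argmax = None
        return dx


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, X, Y, Z)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        self._cache = (xhat, inv_std)
        return (self.gamma.data[None, :, None, None, None] * xhat
                + self.beta.data[None, :, None, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.gamma.grad = (dout * xhat).sum(axis=axes)
        self.beta.grad = dout.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        dxhat = dout * g
        if self.training:
            dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                  - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m)
            dx *= inv_std[None, :, None, None, None]
        else:
            dx = dxhat * inv_std[None, :, None, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = np.where(self._mask, dout, 0.0).astype(np.float32)
        self._mask = None
        return dx


class Sigmoid(Module):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        self._out = out.astype(np.float32)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._out is not None
        dx = (dout * self._out * (1.0 - self._out)).astype(np.float32)
        self._out = None
        return dx


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx.astype(np.float32)


class Flatten(Module):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        return dout.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (x @ self.weight.data + self.bias.data).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.weight.grad = self._x.T @ dout
        self.bias.grad = dout.sum(axis=0)
        dx = dout @ self.weight.data.T
        self._x = None
        return dx.astype(np.float32)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer with an adjustable learning rate (for step decay)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def ce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean element-wise binary cross-entropy between probability and
    binary-target volumes.

    Probabilities are clipped to ``[eps, 1 - eps]`` before taking logs, so
    a prediction that exactly equals its binary target contributes
    ``-ln(1 - eps)`` per element rather than NaN.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs target {target.shape}")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically fused sigmoid + binary cross-entropy.

    Returns ``(mean loss, gradient w.r.t. the logits)``; the gradient of the
    mean loss is ``(sigmoid(z) - t) / n``.
    """
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {t.shape}")
    # log(1 + e^-|z|) + max(z, 0) - z*t is stable for both signs of z
    loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * t))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - t) / z.size).astype(np.float32)
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error (kg^2 when inputs are weights in kg)."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))
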