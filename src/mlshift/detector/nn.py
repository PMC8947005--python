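"""Minimal CPU neural-network layers with explicit backprop.

Just enough machinery for the two-stage keypoint detector: im2col-based 2-D
convolution, ReLU, fully connected layers, nearest-neighbour 2x upsampling
and an Adam optimizer. Parameters live in :class:`Param` objects holding the
value and its accumulated gradient; each layer caches what its backward pass
needs. Everything is float32 and deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "Linear", "Upsample2x", "Adam", "Module"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base: exposes the flat parameter list for the optimizer."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out += v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out += item.params()
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"state has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, C*kh*kw, out_h*out_w)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hh, ww = x.shape[2], x.shape[3]
    out_h = (hh - kh) // stride + 1
    out_w = (ww - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * out_h : stride,
                                 j : j + stride * out_w : stride]
    return cols.reshape(n, c * kh * kw, out_h * out_w), (out_h, out_w)


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hh, ww = h + 2 * pad, w + 2 * pad
    out_h = (hh - kh) // stride + 1
    out_w = (ww - kw) // stride + 1
    dx = np.zeros((n, c, hh, ww), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, out_h, out_w)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * out_h : stride,
               j : j + stride * out_w : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.weight = Param(rng.normal(0.0, scale, (c_out, c_in, k, k)))
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.k, self.k, self.stride, self.pad)
        w2 = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = np.einsum("of,nfp->nop", w2, cols, optimize=True)
        out += self.bias.value[None, :, None]
        self._cache = (cols, x.shape)
        n = x.shape[0]
        return out.reshape(n, -1, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c_out, oh, ow = dy.shape
        dy2 = dy.reshape(n, c_out, oh * ow)
        w2 = self.weight.value.reshape(c_out, -1)
        self.weight.grad += np.einsum("nop,nfp->of", dy2, cols,
                                      optimize=True).reshape(self.weight.value.shape)
        self.bias.grad += dy2.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", w2, dy2, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.weight = Param(rng.normal(0.0, scale, (n_out, n_in)))
        self.bias = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling (for the FPN top-down path)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam with the standard bias correction; weight decay optional."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
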