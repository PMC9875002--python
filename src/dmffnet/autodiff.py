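"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives a convolutional encoder-decoder needs:
broadcast arithmetic, reductions, 2D convolution (im2col), batch
normalization, 2x2 max pooling, bilinear 2x upsampling, channel
concatenation/slicing and the pointwise non-linearities. Every primitive
carries a hand-derived backward pass; the test suite checks each against
central finite differences.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar result. The graph is built eagerly and freed when the Python
references go away.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries from ``start`` along ``axis``."""
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def bwd(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accum(full)

        return Tensor._make(self.data[sl], (self,), bwd)

    # -- non-linearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def hardswish(self):
        """x * clip(x + 3, 0, 6) / 6 (piecewise-quadratic swish approximation)."""
        x = self.data
        inner = np.clip(x + 3.0, 0.0, 6.0)
        out = x * inner / 6.0
        dydx = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))

        def bwd(g):
            self._accum(g * dydx)

        return Tensor._make(out, (self,), bwd)

    # -- structured ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """NCHW 2D convolution (cross-correlation) via im2col."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        OC, IC, kh, kw = w.shape
        if IC != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {IC}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        OH = (H + 2 * p - kh) // s + 1
        OW = (W + 2 * p - kw) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # N,C,OH,OW,kh,kw
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, OH * OW)
        w2 = w.reshape(OC, C * kh * kw)
        out = np.einsum("of,nfl->nol", w2, cols, optimize=True)
        out = out.reshape(N, OC, OH, OW)
        if bias is not None:
            out = out + bias.data.reshape(1, OC, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def bwd(g):
            g2 = g.reshape(N, OC, OH * OW)
            if weight.requires_grad:
                dw = np.einsum("nol,nfl->of", g2, cols, optimize=True)
                weight._accum(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.einsum("of,nol->nfl", w2, g2, optimize=True)
                dcols = dcols.reshape(N, C, kh, kw, OH, OW)
                dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += dcols[:, :, i, j]
                self._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

        return Tensor._make(out, parents, bwd)

    def batchnorm2d(self, gamma: "Tensor", beta: "Tensor",
                    running_mean: np.ndarray, running_var: np.ndarray,
                    training: bool, momentum: float = 0.1, eps: float = 1e-5):
        """Per-channel batch normalization; updates running stats in place."""
        x = self.data
        C = x.shape[1]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
        out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gi = gamma.data.reshape(1, C, 1, 1) * inv.reshape(1, C, 1, 1)
                if training:
                    m = x.shape[0] * x.shape[2] * x.shape[3]
                    gm = g.sum(axis=(0, 2, 3), keepdims=True) / m
                    gxm = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                    self._accum(gi * (g - gm - xhat * gxm))
                else:
                    self._accum(gi * g)

        return Tensor._make(out, (self, gamma, beta), bwd)

    def maxpool2x2(self):
        x = self.data
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
        win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(N, C, H // 2, W // 2, 4)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

        def bwd(g):
            dwin = np.zeros_like(win)
            np.put_along_axis(dwin, arg[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(dx.reshape(N, C, H, W))

        return Tensor._make(out, (self,), bwd)

    def upsample_bilinear2x(self):
        """Bilinear 2x upsampling, half-pixel centers (align_corners=False)."""
        x = self.data
        N, C, H, W = x.shape
        iy0, iy1, wy0, wy1 = _up2x_coeffs(H)
        ix0, ix1, wx0, wx1 = _up2x_coeffs(W)
        rows = x[:, :, iy0, :] * wy0[None, None, :, None] + \
            x[:, :, iy1, :] * wy1[None, None, :, None]
        out = rows[:, :, :, ix0] * wx0[None, None, None, :] + \
            rows[:, :, :, ix1] * wx1[None, None, None, :]

        def bwd(g):
            drows = np.zeros((N, C, 2 * H, W))
            np.add.at(drows.transpose(3, 0, 1, 2), ix0,
                      (g * wx0[None, None, None, :]).transpose(3, 0, 1, 2))
            np.add.at(drows.transpose(3, 0, 1, 2), ix1,
                      (g * wx1[None, None, None, :]).transpose(3, 0, 1, 2))
            dx = np.zeros((N, C, H, W))
            np.add.at(dx.transpose(2, 0, 1, 3), iy0,
                      (drows * wy0[None, None, :, None]).transpose(2, 0, 1, 3))
            np.add.at(dx.transpose(2, 0, 1, 3), iy1,
                      (drows * wy1[None, None, :, None]).transpose(2, 0, 1, 3))
            self._accum(dx)

        return Tensor._make(out, (self,), bwd)


def _up2x_coeffs(n: int):
    """Source indices and weights for 1D bilinear 2x upsampling."""
    dst = np.arange(2 * n)
    src = (dst + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
    i1 = np.clip(i0 + 1, 0, n - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    frac[src > n - 1] = 0.0
    return i0, i1, 1.0 - frac, frac


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )
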