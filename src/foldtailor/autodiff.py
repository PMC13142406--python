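"""Minimal reverse-mode automatic differentiation over numpy arrays.

The contact-map predictor and the sequence optimizer need gradients of a
scalar loss with respect to relaxed one-hot sequence entries.  This module
provides a small tape-based :class:`Tensor` supporting exactly the operations
the predictor trunk/head and the optimizer require: broadcasting arithmetic,
elementwise nonlinearities, reductions, 1D/2D convolution, max-pooling,
slicing/concatenation, cumulative sums and softmax.  Gradients are checked
against central finite differences in the test suite.

Only float64 arrays are used; there is no GPU path and no graph reuse —
build a fresh graph per forward pass and call :meth:`Tensor.backward` once.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concat", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        out = Tensor(
            np.maximum(self.data, 0.0), requires_grad=self.requires_grad, parents=(self,)
        )
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out = Tensor(
            np.logaddexp(0.0, self.data), requires_grad=self.requires_grad, parents=(self,)
        )
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def minimum_const(self, c: float):
        """Elementwise min(x, c); gradient passes where x < c."""
        out = Tensor(
            np.minimum(self.data, c), requires_grad=self.requires_grad, parents=(self,)
        )
        out._backward = lambda g: self._accum(g * (self.data < c))
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        out._backward = bw
        return out

    def cumsum(self, axis: int):
        out = Tensor(
            np.cumsum(self.data, axis=axis),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw(g):
            rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
            self._accum(rev)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(
            self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,)
        )
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(
            self.data.transpose(axes), requires_grad=self.requires_grad, parents=(self,)
        )
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            self._accum(grad)

        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bw
        return out

    # -- convolutions ------------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor" | None = None, pad: str = "same"):
        """1D convolution. self: (C_in, L); weight: (C_out, C_in, K).

        pad="same" zero-pads to keep length L; pad="valid" yields L-K+1.
        """
        w = as_tensor(weight)
        c_out, c_in, k = w.data.shape
        x = self.data
        if pad == "same":
            p = (k - 1) // 2
            xp = np.pad(x, ((0, 0), (p, k - 1 - p)))
        elif pad == "valid":
            p = 0
            xp = x
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown padding {pad!r}")
        lout = xp.shape[1] - k + 1
        win = sliding_window_view(xp, k, axis=1)  # (C_in, Lout, K)
        y = np.einsum("clk,ock->ol", win, w.data, optimize=True)
        parents = [self, w]
        if bias is not None:
            b = as_tensor(bias)
            y = y + b.data[:, None]
            parents.append(b)
        out = Tensor(
            y,
            requires_grad=any(t.requires_grad for t in parents),
            parents=tuple(parents),
        )

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("ol,clk->ock", g, win, optimize=True))
            if bias is not None and parents[2].requires_grad:
                parents[2]._accum(g.sum(axis=1))
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for kk in range(k):
                    dxp[:, kk : kk + lout] += np.einsum(
                        "ol,oc->cl", g, w.data[:, :, kk], optimize=True
                    )
                if pad == "same":
                    self._accum(dxp[:, p : p + x.shape[1]])
                else:
                    self._accum(dxp)

        out._backward = bw
        return out

    def maxpool1d(self, k: int):
        """Non-overlapping max pooling along axis 1 of (C, L); L % k == 0."""
        c, length = self.data.shape
        if length % k:
            raise ValueError(f"length {length} not divisible by pool size {k}")
        xr = self.data.reshape(c, length // k, k)
        idx = np.argmax(xr, axis=2)
        out = Tensor(xr.max(axis=2), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            grad = np.zeros_like(xr)
            np.put_along_axis(grad, idx[:, :, None], g[:, :, None], axis=2)
            self._accum(grad.reshape(c, length))

        out._backward = bw
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None, dilation: int = 1):
        """2D "same" convolution. self: (C_in, H, W); weight: (C_out, C_in, k, k)."""
        w = as_tensor(weight)
        c_out, c_in, kh, kw = w.data.shape
        d = dilation
        ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
        x = self.data
        h, wd = x.shape[1], x.shape[2]
        xp = np.pad(x, ((0, 0), (ph, d * (kh - 1) - ph), (pw, d * (kw - 1) - pw)))
        y = np.zeros((c_out, h, wd))
        for i in range(kh):
            for j in range(kw):
                y += np.einsum(
                    "chw,oc->ohw",
                    xp[:, i * d : i * d + h, j * d : j * d + wd],
                    w.data[:, :, i, j],
                    optimize=True,
                )
        parents = [self, w]
        if bias is not None:
            b = as_tensor(bias)
            y = y + b.data[:, None, None]
            parents.append(b)
        out = Tensor(
            y,
            requires_grad=any(t.requires_grad for t in parents),
            parents=tuple(parents),
        )

        def bw(g):
            if w.requires_grad:
                dw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        dw[:, :, i, j] = np.einsum(
                            "ohw,chw->oc",
                            g,
                            xp[:, i * d : i * d + h, j * d : j * d + wd],
                            optimize=True,
                        )
                w._accum(dw)
            if bias is not None and parents[2].requires_grad:
                parents[2]._accum(g.sum(axis=(1, 2)))
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i * d : i * d + h, j * d : j * d + wd] += np.einsum(
                            "ohw,oc->chw", g, w.data[:, :, i, j], optimize=True
                        )
                self._accum(dxp[:, ph : ph + h, pw : pw + wd])

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )

    def bw(g):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def grad_check(fn, x: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Return (analytic, numeric) gradients of scalar fn at x (test helper)."""
    t = Tensor(x.copy(), requires_grad=True)
    out = fn(t)
    out.backward()
    analytic = t.grad.copy()
    numeric = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    num_flat = numeric.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(Tensor(x)).data.item()
        flat[i] = orig - eps
        lo = fn(Tensor(x)).data.item()
        flat[i] = orig
        num_flat[i] = (hi - lo) / (2 * eps)
    return analytic, numeric
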