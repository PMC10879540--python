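"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical engine behind every network block in the
package: a :class:`Tensor` wraps an ``ndarray`` and records the operations
applied to it, and :meth:`Tensor.backward` propagates gradients through the
recorded graph.  Only the operations the architecture needs are provided
(broadcast arithmetic, matmul, 2-D/1-D convolution via im2col, max-pooling,
reductions, sigmoid/ReLU, concatenation, nearest/bilinear 2x upsampling).

Gradients are retained on every node, not just leaves, so class-activation
mapping can read the gradient at an intermediate feature map directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Module", "concat", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ #
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor; seeds with ones if grad is None."""
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---------------------------- arithmetic -------------------------- #
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # ---------------------------- shape ops --------------------------- #
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        mx = self.data.max(axis=axis, keepdims=True)
        out = Tensor(mx if keepdims else np.squeeze(mx, axis=axis), _prev=(self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == mx).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accum(mask * g)

        out._backward = bw
        return out

    # -------------------------- nonlinearities ------------------------ #
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # ------------------------- conv / pooling ------------------------- #
    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int = 1,
               padding: int = 0) -> "Tensor":
        """NCHW convolution. weight: (Cout, Cin, KH, KW); bias: (Cout,) or None."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Cout, Cin, KH, KW = w.shape
        if Cin != C:
            raise ValueError(f"conv2d: expected {Cin} input channels, got {C}")
        OH = (H + 2 * padding - KH) // stride + 1
        OW = (W + 2 * padding - KW) // stride + 1
        cols = _im2col(x, KH, KW, stride, padding, OH, OW)  # (N, C*KH*KW, OH*OW)
        wm = w.reshape(Cout, -1)
        y = np.einsum("ok,nkp->nop", wm, cols, optimize=True).reshape(N, Cout, OH, OW)
        if bias is not None:
            y += bias.data.reshape(1, Cout, 1, 1)
        prev = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(y, _prev=prev)

        def bw(g):
            gm = g.reshape(N, Cout, OH * OW)
            weight._accum(np.einsum("nop,nkp->ok", gm, cols, optimize=True).reshape(w.shape))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gcols = np.einsum("ok,nop->nkp", wm, gm, optimize=True)
            self._accum(_col2im(gcols, x.shape, KH, KW, stride, padding, OH, OW))

        out._backward = bw
        return out

    def maxpool2d(self, kernel: int, stride: int, padding: int = 0) -> "Tensor":
        x = self.data
        N, C, H, W = x.shape
        OH = (H + 2 * padding - kernel) // stride + 1
        OW = (W + 2 * padding - kernel) // stride + 1
        if OH < 1 or OW < 1:
            raise ValueError("maxpool2d: spatial dims too small for the window/stride")
        xp = np.full((N, C, H + 2 * padding, W + 2 * padding), -np.inf)
        xp[:, :, padding:padding + H, padding:padding + W] = x
        wins = np.empty((N, C, kernel * kernel, OH, OW))
        idx = 0
        for i in range(kernel):
            for j in range(kernel):
                wins[:, :, idx] = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
                idx += 1
        arg = wins.argmax(axis=2)
        out = Tensor(np.take_along_axis(wins, arg[:, :, None], axis=2)[:, :, 0], _prev=(self,))

        def bw(g):
            gp = np.zeros_like(xp)
            ii, jj = np.divmod(arg, kernel)
            oh = np.arange(OH)[:, None]
            ow = np.arange(OW)[None, :]
            rows = ii + stride * oh  # (N,C,OH,OW)
            colsx = jj + stride * ow
            n_idx = np.arange(N)[:, None, None, None]
            c_idx = np.arange(C)[None, :, None, None]
            np.add.at(gp, (n_idx, c_idx, rows, colsx), g)
            self._accum(gp[:, :, padding:padding + H, padding:padding + W])

        out._backward = bw
        return out

    def upsample2x(self, mode: str = "nearest") -> "Tensor":
        x = self.data
        N, C, H, W = x.shape
        if mode == "nearest":
            y = x.repeat(2, axis=2).repeat(2, axis=3)
            out = Tensor(y, _prev=(self,))

            def bw(g):
                self._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

            out._backward = bw
            return out
        if mode == "bilinear":
            # align_corners=False bilinear doubling expressed as a sparse linear map
            mat = _bilinear2x_matrix(H)
            matw = mat if W == H else _bilinear2x_matrix(W)
            y = np.einsum("ij,ncjk,lk->ncil", mat, x, matw, optimize=True)
            out = Tensor(y, _prev=(self,))

            def bw(g):
                self._accum(np.einsum("ij,ncil,lk->ncjk", mat, g, matw, optimize=True))

            out._backward = bw
            return out
        raise ValueError(f"unknown upsample mode: {mode!r}")


def _im2col(x, KH, KW, stride, padding, OH, OW):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((N, C, KH, KW, OH, OW))
    for i in range(KH):
        for j in range(KW):
            cols[:, :, i, j] = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
    return cols.reshape(N, C * KH * KW, OH * OW)


def _col2im(cols, xshape, KH, KW, stride, padding, OH, OW):
    N, C, H, W = xshape
    cols = cols.reshape(N, C, KH, KW, OH, OW)
    gp = np.zeros((N, C, H + 2 * padding, W + 2 * padding))
    for i in range(KH):
        for j in range(KW):
            gp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += cols[:, :, i, j]
    return gp[:, :, padding:padding + H, padding:padding + W]


_BILIN_CACHE: dict[int, np.ndarray] = {}


def _bilinear2x_matrix(n: int) -> np.ndarray:
    """(2n x n) interpolation matrix for align_corners=False 2x upsampling."""
    if n in _BILIN_CACHE:
        return _BILIN_CACHE[n]
    mat = np.zeros((2 * n, n))
    for o in range(2 * n):
        src = (o + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c, hi_c = np.clip(lo, 0, n - 1), np.clip(lo + 1, 0, n - 1)
        mat[o, lo_c] += 1.0 - frac
        mat[o, hi_c] += frac
    _BILIN_CACHE[n] = mat
    return mat


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between raw logits (N,K) and integer labels (N,)."""
    n = logits.shape[0]
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, detached
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    picked = logp.data[np.arange(n), labels]
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), labels] = 1.0
    loss = (logp * Tensor(-onehot / n)).sum()
    # sanity: picked only used for finiteness diagnostics by callers
    _ = picked
    return loss


# ---------------------------------------------------------------------- #
#  Module system
# ---------------------------------------------------------------------- #
class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny nn.Module analogue: parameter registration, train/eval, state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mk}.")

    def named_buffers(self, prefix: str = ""):
        for k, v in getattr(self, "_buffers", {}).items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{mk}.")

    def register_buffer(self, name: str, value: np.ndarray):
        if not hasattr(self, "_buffers"):
            object.__setattr__(self, "_buffers", {})
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def train(self):
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        d = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        d.update({f"buffer:{k}": np.asarray(v).copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for key, val in d.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(val, dtype=np.float64).reshape(params[name].data.shape)
            else:
                self._load_buffer(name, np.asarray(val))

    def _load_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            obj = obj._modules[p]
        obj._set_buffer(parts[-1], value)
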