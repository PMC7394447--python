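"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the primitives needed by the models in this package are implemented:
elementwise arithmetic with broadcasting, matmul, valid 2-D convolution,
reductions, reshaping/indexing, ELU/ReLU/sigmoid, softmax and a fused
softmax-cross-entropy. Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "parameter", "conv2d", "softmax", "softmax_cross_entropy",
           "elu", "relu", "sigmoid", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self._grad_owned = False
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------ graph ops
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        # first contribution is stored as-is (it may alias another node's
        # grad); the second makes an owned copy, later ones add in place
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data**(exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape) + 0.0)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape) + 0.0)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)


def parameter(array) -> Tensor:
    return Tensor(np.asarray(array), requires_grad=True)


# ----------------------------------------------------------------- activations
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * np.expm1(x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, out_data + alpha))

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Per-row cross entropy between softmax(logits) and one-hot targets.

    ``onehot`` is a constant array of the same shape as ``logits``; the
    class axis is the last one. Returns a Tensor of shape logits.shape[:-1].
    """
    onehot = np.asarray(onehot)
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - lse
    out_data = -(onehot * logp).sum(axis=-1)

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            logits._accumulate(g[..., None] * (probs - onehot))

    return Tensor._make(out_data, (logits,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Every label of each input must appear in the output or in the other
    input (no internal diagonals/traces), which holds for all contractions
    used by the models and makes the gradient another einsum.
    """
    ins, out = subscripts.replace(" ", "").split("->")
    sub_a, sub_b = ins.split(",")
    if not (set(sub_a) <= set(out + sub_b) and set(sub_b) <= set(out + sub_a)):
        raise ValueError(f"unsupported einsum spec {subscripts!r}")
    out_data = np.einsum(subscripts, a.data, b.data, optimize=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out},{sub_b}->{sub_a}", g, b.data,
                                    optimize=True))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out},{sub_a}->{sub_b}", g, a.data,
                                    optimize=True))

    return Tensor._make(out_data, (a, b), backward)


# ---------------------------------------------------------------- convolution
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1) -> Tensor:
    """Valid (no padding) 2-D convolution.

    x: (B, C, H, W); w: (O, C, k, k); b: (O,) or None. Output
    (B, O, Ho, Wo) with Ho = (H - k)//stride + 1.
    """
    B, C, H, W = x.shape
    O, Cw, k, _ = w.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    if H < k or W < k:
        raise ValueError(f"input {H}x{W} smaller than kernel {k}x{k}")
    windows = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = np.einsum("bchwij,ocij->bohw", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("bohw,bchwij->ocij", g, windows, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        np.einsum("bohw,oc->bchw", g, w.data[:, :, i, j],
                                  optimize=True)
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)
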