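"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based scalar-output autograd sized exactly for the operations the
synergy network needs: broadcast arithmetic, 2-D matrix products, batched
last-two-axes transposes, reshapes, row gathers, sliding convolution
windows, layer normalization and the GELU / SiLU activations. Gradients
are dense NumPy arrays accumulated in a reverse topological pass.

Every operation's vector-Jacobian product is exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

# Python floats, not numpy scalars: float64 scalars would upcast float32 graphs
_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


class Tensor:
    """A NumPy array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        # ops emit fresh gradient arrays, so aliasing the first one is safe;
        # later contributions allocate via `+` anyway
        grad = np.asarray(grad)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + grad

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(self._lift(other), -1.0))

    def __rsub__(self, other):
        return add(self._lift(other), mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return a._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return a._make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """2-D matrix product (batch dims are folded by callers via reshape)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul expects 2-D operands")
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return a._make(out_data, (a, b), backward)


def reshape(x, shape) -> Tensor:
    x = Tensor._lift(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.shape))

    return x._make(out_data, (x,), backward)


def swap_last2(x) -> Tensor:
    """Transpose the last two axes (the N-D / D-N permutation)."""
    x = Tensor._lift(x)
    out_data = np.swapaxes(x.data, -1, -2)

    def backward(g):
        x._accumulate(np.swapaxes(g, -1, -2))

    return x._make(out_data, (x,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(x, idx) -> Tensor:
    """Select rows ``x[idx]``; the gradient scatter-adds back."""
    x = Tensor._lift(x)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accumulate(gx)

    return x._make(out_data, (x,), backward)


def sum_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = Tensor._lift(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape))

    return x._make(out_data, (x,), backward)


def mean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = Tensor._lift(x)
    n = x.data.size if axis is None else x.shape[axis]
    return mul(sum_(x, axis=axis, keepdims=keepdims), 1.0 / n)


def gelu(x) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = Tensor._lift(x)
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * phi

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
        x._accumulate(g * (phi + x.data * pdf))

    return x._make(out_data, (x,), backward)


def silu(x) -> Tensor:
    """SiLU / Swish activation: x * sigmoid(x)."""
    x = Tensor._lift(x)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * sig

    def backward(g):
        x._accumulate(g * sig * (1.0 + x.data * (1.0 - sig)))

    return x._make(out_data, (x,), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    x, gamma, beta = Tensor._lift(x), Tensor._lift(gamma), Tensor._lift(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_sd
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(
                _unbroadcast(g * xhat, gamma.shape)
            )
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx_hat = g * gamma.data
            m1 = gx_hat.mean(axis=-1, keepdims=True)
            m2 = (gx_hat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv_sd * (gx_hat - m1 - xhat * m2))

    out = Tensor(out_data)
    if any(t.requires_grad for t in (x, gamma, beta)):
        out.requires_grad = True
        out._parents = (x, gamma, beta)
        out._backward = backward
    return out


def conv_windows(x, kernel: int) -> Tensor:
    """Length-preserving sliding windows for 1-D convolution.

    ``x`` has shape (B, L, C). The sequence is zero-padded with
    ``(kernel-1)//2`` positions on the left and ``kernel//2`` on the right,
    then unfolded into shape (B, L, kernel*C); a matmul with a
    ``(kernel*C, C_out)`` weight completes the convolution.
    """
    x = Tensor._lift(x)
    if x.data.ndim != 3:
        raise ValueError("conv_windows expects (batch, length, channels)")
    batch, length, channels = x.shape
    pad_l = (kernel - 1) // 2
    pad_r = kernel // 2
    padded = np.zeros((batch, length + pad_l + pad_r, channels), dtype=x.dtype)
    padded[:, pad_l : pad_l + length, :] = x.data
    windows = np.empty((batch, length, kernel, channels), dtype=x.dtype)
    for t in range(kernel):
        windows[:, :, t, :] = padded[:, t : t + length, :]
    out_data = windows.reshape(batch, length, kernel * channels)

    def backward(g):
        g = g.reshape(batch, length, kernel, channels)
        gpad = np.zeros_like(padded)
        for t in range(kernel):
            gpad[:, t : t + length, :] += g[:, :, t, :]
        x._accumulate(gpad[:, pad_l : pad_l + length, :])

    return x._make(out_data, (x,), backward)
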