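"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains its networks with a small tape-based autodiff engine:
every operation returns a :class:`Tensor` that remembers its parents and a
closure propagating the upstream gradient.  Only the operations the model
needs are provided (elementwise arithmetic with broadcasting, matmul,
reductions, reshapes, activations, 2-D convolution, 2x2 pooling, dropout,
batch normalisation and a fused softmax cross-entropy).  Convolution is
implemented with stride-tricks windows and ``einsum``; its input gradient
scatters through the kernel taps, so no im2col buffer is materialised in
the backward pass.

All gradients here are checked against central finite differences in the
test-suite; treat that check as the contract when adding new primitives.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "avg_pool2x2",
    "max_pool2x2",
    "batch_norm",
    "dropout",
    "softmax_cross_entropy",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    # -- shape ----------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._result(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._result(out_data, (self, other), backward)

    # -- reductions / reshapes ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        return Tensor._result(out_data, (self,), backward)

    # -- activations ----------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    # -- graph traversal ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always true)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# free-standing primitives
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accum(g[tuple(index)])

    return Tensor._result(out_data, tuple(tensors), backward)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: tuple[int, int] = (0, 0),
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride, per-axis zero padding.

    The forward pass is a single ``einsum`` over sliding windows; the backward
    pass computes the weight gradient from the saved window view and scatters
    the input gradient tap-by-tap (kh*kw strided adds).
    """
    xd, wd = x.data, weight.data
    batch, cin, h, w = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    ph, pw = padding
    if h + 2 * ph < kh or w + 2 * pw < kw:
        raise ValueError("kernel larger than (padded) input")
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("bchwij,ocij->bohw", windows, wd, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    h_out, w_out = out.shape[2:]

    def backward(g):
        if weight.requires_grad:
            weight._accum(np.einsum("bohw,bchwij->ocij", g, windows, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :,
                        :,
                        i : i + stride * h_out : stride,
                        j : j + stride * w_out : stride,
                    ] += np.einsum("bohw,oc->bchw", g, wd[:, :, i, j], optimize=True)
            gx = gxp[:, :, ph : ph + h, pw : pw + w]
            x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out, parents, backward)


def avg_pool2x2(x: Tensor) -> Tensor:
    batch, ch, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2x2 needs even spatial dimensions")
    out = x.data.reshape(batch, ch, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx)

    return Tensor._result(out, (x,), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    batch, ch, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 needs even spatial dimensions")
    xr = (
        x.data.reshape(batch, ch, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(batch, ch, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)  # first occurrence wins on ties
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(batch, ch, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(batch, ch, h, w)
        )
        x._accum(gx)

    return Tensor._result(out, (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    axes: tuple[int, ...] = (0, 2, 3),
) -> Tensor:
    """Batch normalisation over ``axes`` with in-place running-stat updates.

    ``gamma``/``beta`` and the running statistics are shaped for broadcasting
    against ``x`` (e.g. (1, C, 1, 1) for NCHW input).  In training mode the
    batch statistics are used and backpropagated through; in evaluation mode
    the map is a fixed affine transform of its input.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=axes, keepdims=True)
        var = xd.var(axis=axes, keepdims=True)
        n = xd.size // mean.size
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance for the running estimate, as is conventional
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean) * inv_std
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if not x.requires_grad:
            return
        gxhat = g * gamma.data
        if training:
            m = xd.size // mean.size
            gx = (
                inv_std
                / m
                * (
                    m * gxhat
                    - gxhat.sum(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
                )
            )
        else:
            gx = gxhat * inv_std
        x._accum(gx)

    return Tensor._result(out, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: identity at evaluation time."""
    if not training or rate == 0.0:
        return x
    if rate >= 1.0:
        mask = np.zeros_like(x.data)
    else:
        mask = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._result(x.data * mask, (x,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain array (no gradient tracking)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    return Tensor._result(np.asarray(loss), (logits,), backward)
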