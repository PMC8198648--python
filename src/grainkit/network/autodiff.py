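"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The feature extractor processes one image at a time (boards have heterogeneous
sizes, so there is no natural batch axis); every op here therefore works on
single-sample arrays, image tensors being laid out channel-first ``(C, H, W)``.
Gradients accumulate in ``Tensor.grad`` after :meth:`Tensor.backward`.

Only the ops the trunk needs are provided: broadcast add/mul, matmul, relu,
sigmoid, 2-D convolution (im2col), max-pooling, reductions, slicing, reshape
and concatenation.  Everything is float64 — accuracy over speed, sized for the
tiny trunk configurations used in tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; seeds with ones if grad is None."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __matmul__(self, other):
        other = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=back)

    def sigmoid(self):
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(-self.data))
        # clamp to the open interval at float resolution: gates must stay
        # strictly inside (0, 1) even when the preactivation saturates
        out = np.clip(out, np.finfo(np.float64).tiny, 1.0 - np.finfo(np.float64).eps / 2)

        def back(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=back)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    def __getitem__(self, idx):
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=back)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def back(g):
            if not self.requires_grad:
                return
            expanded = out if keepdims or axis is None else np.expand_dims(out, axis)
            mask = self.data == expanded
            # gradient split evenly among ties (a valid subgradient)
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g / counts)

        return Tensor(out, parents=(self,), backward=back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=back,
    )


def _im2col(padded: np.ndarray, kh: int, kw: int, stride: int):
    """(C, Hp, Wp) -> columns (H_out*W_out, C*kh*kw) plus output geometry."""
    win = sliding_window_view(padded, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    c, ho, wo = win.shape[0], win.shape[1], win.shape[2]
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation): x (C_in,H,W), w (C_out,C_in,kh,kw)."""
    c_out, c_in, kh, kw = w.data.shape
    if x.data.shape[0] != c_in:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[0]} channels, kernel expects {c_in}"
        )
    padded = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, ho, wo = _im2col(padded, kh, kw, stride)
    wmat = w.data.reshape(c_out, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(ho, wo, c_out).transpose(2, 0, 1)

    def back(g):
        gmat = g.transpose(1, 2, 0).reshape(-1, c_out)  # (L, C_out)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(ho, wo, c_in, kh, kw)
            dpad = np.zeros_like(padded)
            for i in range(kh):
                for j in range(kw):
                    dpad[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        dcols[:, :, :, i, j].transpose(2, 0, 1)
                    )
            if pad:
                dpad = dpad[:, pad:-pad, pad:-pad]
            x._accum(dpad)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=back)


def maxpool2d(x: Tensor, kernel: int, stride: int, pad: int = 0) -> Tensor:
    """Max pooling over (H, W) of a (C, H, W) tensor."""
    if pad:
        padded = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    else:
        padded = x.data
    win = sliding_window_view(padded, (kernel, kernel), axis=(1, 2))[:, ::stride, ::stride]
    c, ho, wo = win.shape[:3]
    flat = win.reshape(c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[..., None], axis=3)[..., 0]

    def back(g):
        if not x.requires_grad:
            return
        dpad = np.zeros_like(padded)
        ci, hi, wi = np.meshgrid(np.arange(c), np.arange(ho), np.arange(wo), indexing="ij")
        rows = hi * stride + idx // kernel
        cols = wi * stride + idx % kernel
        np.add.at(dpad, (ci, rows, cols), g)
        if pad:
            dpad = dpad[:, pad:-pad, pad:-pad]
        x._accum(dpad)

    return Tensor(out, parents=(x,), backward=back)
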