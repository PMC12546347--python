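"""Minimal reverse-mode autodiff over numpy arrays.

A tape-free define-by-run graph: every operation returns a new
:class:`Tensor` holding the forward value and a closure that accumulates
gradients into its parents.  The op set is exactly what the detection
blocks need — broadcasted arithmetic, matmul, convolution via an explicit
im2col (``unfold``), per-position dynamic kernel mixing, pooling, nearest
upsampling, softmax and stable binary cross-entropy.  Dtype follows the
inputs, so gradient checks can run in float64 while training runs float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "unfold", "conv2d", "dynamic_mix"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add ``grad`` into this tensor's gradient buffer.

        ``fresh=True`` promises the caller hands over exclusive ownership of
        ``grad`` (a newly computed array or a view nobody else accumulates
        into), letting the first accumulation skip a copy.
        """
        if self.grad is None:
            self.grad = grad if fresh else np.array(grad, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bwd(g):
            ga = _unbroadcast(g, self.data.shape) if self.requires_grad else None
            gb = _unbroadcast(g, other.data.shape) if other.requires_grad else None
            if ga is not None and gb is not None and ga is gb:
                gb = np.array(gb, copy=True)
            if ga is not None:
                self._accum(ga, fresh=ga is not g)
            if gb is not None:
                other._accum(gb, fresh=gb is not g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), fresh=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), fresh=True)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor._make(self.data**exponent, (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0), fresh=True)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(np.matmul(self.data, other.data), (self, other), None)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape), fresh=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape), fresh=True)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ unary ops
    def relu(self) -> "Tensor":
        out = Tensor._make(np.maximum(self.data, 0.0), (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0), fresh=True)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y), fresh=True)

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        y = np.exp(np.clip(self.data, -60, 60))
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y, fresh=True)

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor._make(np.log(self.data), (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data, fresh=True)

        out._backward = bwd
        return out

    def softplus(self) -> "Tensor":
        z = self.data
        y = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-np.clip(z, -60, 60))), fresh=True)

        out._backward = bwd
        return out

    # -------------------------------------------------------- shape & slice
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(src), fresh=True)

        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv), fresh=True)

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor._make(self.data[idx], (self,), None)
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis))) for p in parts)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # slices index disjoint views: plain += suffices
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full, fresh=True)

        out._backward = bwd
        return out

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        src_shape = self.data.shape

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, src_shape).copy(), fresh=True)
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, src_shape).copy(), fresh=True)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_spatial(self) -> "Tensor":
        """Global max over the two trailing spatial axes of an NCHW tensor.

        Gradient flows to the first maximal position per (n, c) only, which
        keeps the backward pass deterministic under ties.
        """
        n, c, h, w = self.data.shape
        flat = self.data.reshape(n, c, h * w)
        idx = np.argmax(flat, axis=2)
        val = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        out = Tensor._make(val, (self,), None)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(flat)
                np.put_along_axis(full, idx[:, :, None], g[:, :, None], axis=2)
                self._accum(full.reshape(n, c, h, w), fresh=True)

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot), fresh=True)

        out._backward = bwd
        return out

    # ------------------------------------------------------- spatial resizing
    def upsample_nearest2(self) -> "Tensor":
        n, c, h, w = self.data.shape
        y = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)), fresh=True)

        out._backward = bwd
        return out

    def adaptive_avg_pool(self, out_hw: tuple[int, int]) -> "Tensor":
        """Area-adaptive average pooling to an ``(sh, sw)`` grid."""
        n, c, h, w = self.data.shape
        sh, sw = out_hw
        ys = [(int(np.floor(i * h / sh)), int(np.ceil((i + 1) * h / sh))) for i in range(sh)]
        xs = [(int(np.floor(j * w / sw)), int(np.ceil((j + 1) * w / sw))) for j in range(sw)]
        y = np.empty((n, c, sh, sw), dtype=self.data.dtype)
        for i, (y0, y1) in enumerate(ys):
            for j, (x0, x1) in enumerate(xs):
                y[:, :, i, j] = self.data[:, :, y0:y1, x0:x1].mean(axis=(2, 3))
        out = Tensor._make(y, (self,), None)

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            for i, (y0, y1) in enumerate(ys):
                for j, (x0, x1) in enumerate(xs):
                    area = (y1 - y0) * (x1 - x0)
                    full[:, :, y0:y1, x0:x1] += g[:, :, i, j][:, :, None, None] / area
            self._accum(full, fresh=True)

        out._backward = bwd
        return out

    # -------------------------------------------------------------- losses
    def bce_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Elementwise binary cross-entropy on logits (numerically stable)."""
        z, t = self.data, np.asarray(targets)
        loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
        out = Tensor._make(loss, (self,), None)

        def bwd(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
                self._accum(g * (sig - t), fresh=True)

        out._backward = bwd
        return out


# ---------------------------------------------------------------- free ops


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(a), int(b))
                t._accum(g[tuple(sl)], fresh=len(tensors) > 1)

    out._backward = bwd
    return out


def unfold(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """im2col: NCHW → [N, C, k*k, L] patches (zero padding).

    Both forward and backward loop over the k*k kernel offsets with strided
    slicing, which keeps everything vectorized over the spatial extent.
    """
    n, c, h, w = x.data.shape
    k, s, p = kernel, stride, padding
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel {k} with padding {p} exceeds input {h}x{w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = np.empty((n, c, k * k, ho * wo), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            cols[:, :, i * k + j, :] = patch.reshape(n, c, ho * wo)
    out = Tensor._make(cols, (x,), None)

    def bwd(g):
        if not x.requires_grad:
            return
        gp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gp[:, :, i : i + s * ho : s, j : j + s * wo : s] += g[
                    :, :, i * k + j, :
                ].reshape(n, c, ho, wo)
        x._accum(gp[:, :, p : p + h, p : p + w] if p else gp, fresh=True)

    out._backward = bwd
    return out


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D convolution (cross-correlation), weight [Co, Ci/g, k, k]."""
    n, c, h, w = x.data.shape
    co, cig, kh, kw = weight.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    if c != cig * groups or co % groups:
        raise ValueError(
            f"channel mismatch: x has {c}, weight expects {cig * groups} in {groups} groups"
        )
    k, s, p = kh, stride, padding
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    cols = unfold(x, k, stride=s, padding=p)  # [N, C, k2, L]
    cols = cols.reshape(n, groups, cig * k * k, ho * wo)
    wmat = weight.reshape(groups, co // groups, cig * k * k)
    out = wmat @ cols  # [N, G, Co/G, L] via broadcasting
    out = out.reshape(n, co, ho, wo)
    if bias is not None:
        out = out + bias.reshape(1, co, 1, 1)
    return out


def dynamic_mix(xcol: Tensor, kernels: Tensor, groups: int) -> Tensor:
    """Apply per-position, per-group kernels to unfolded patches.

    ``xcol`` is [N, C, k2, L] (from :func:`unfold`), ``kernels`` is
    [N, G, k2, L]; each group's kernel is shared across the C/G channels of
    that group.  Returns [N, C, L].
    """
    n, c, k2, l = xcol.data.shape
    ng, g_, k2b, lb = kernels.data.shape
    if (ng, k2b, lb) != (n, k2, l) or g_ != groups or c % groups:
        raise ValueError("dynamic_mix shape mismatch")
    cpg = c // groups
    xg = xcol.data.reshape(n, groups, cpg, k2, l)
    kg = kernels.data
    y = np.einsum("ngckl,ngkl->ngcl", xg, kg, optimize=True).reshape(n, c, l)
    out = Tensor._make(y, (xcol, kernels), None)

    def bwd(grad):
        go = grad.reshape(n, groups, cpg, l)
        if xcol.requires_grad:
            gx = np.einsum("ngcl,ngkl->ngckl", go, kg, optimize=True)
            xcol._accum(gx.reshape(n, c, k2, l), fresh=True)
        if kernels.requires_grad:
            gk = np.einsum("ngcl,ngckl->ngkl", go, xg, optimize=True)
            kernels._accum(gk, fresh=True)

    out._backward = bwd
    return out
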