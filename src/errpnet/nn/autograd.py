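"""Minimal reverse-mode automatic differentiation over numpy arrays.

The compute core of the package: a :class:`Tensor` wraps an ``ndarray``
together with a gradient slot and the closure that back-propagates into its
parents.  Only the operations the ErrP network needs are implemented —
broadcast arithmetic, (batched) matmul, reshapes, reductions, elementwise
nonlinearities, softmax/log, concatenation, dropout masking and a valid-mode
2-D convolution via im2col.  Gradients of every primitive are checked
against central finite differences in the test suite.

All arithmetic is float64; networks are small (thousands of parameters,
inputs of shape (B, 1, 2, 64)) so precision is preferred over throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph.

    Parameters
    ----------
    data:
        Array payload (copied to float64 on construction).
    requires_grad:
        Whether gradients should be accumulated for this tensor.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (may alias or be a
        # broadcast view); a second contribution forces an owned copy
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(grad, a=self, e=exponent, y=out_data):
            if a.requires_grad:
                a._accum(grad * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- linear algebra -------------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
                if b.data.ndim == 1:  # (.., n) @ (n,) -> grad needs outer
                    ga = grad[..., None] * b.data
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.shape

        def backward(grad, a=self, s=in_shape):
            if a.requires_grad:
                a._accum(grad.reshape(s))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def backward(grad, a=self, axis=axis, keepdims=keepdims, s=in_shape):
            if not a.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, s))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad, a=self, y=out_data):
            if a.requires_grad:
                a._accum(grad * y)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax along ``axis`` (fused primitive)."""
        shift = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shift)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(grad, a=self, y=y, axis=axis):
            if a.requires_grad:
                a._accum(y * (grad - (grad * y).sum(axis=axis, keepdims=True)))

        return Tensor._make(y, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shift = self.data - self.data.max(axis=axis, keepdims=True)
        logz = np.log(np.exp(shift).sum(axis=axis, keepdims=True))
        out = shift - logz

        def backward(grad, a=self, sm=np.exp(out), axis=axis):
            if a.requires_grad:
                a._accum(grad - sm * grad.sum(axis=axis, keepdims=True))

        return Tensor._make(out, (self,), backward)

    def dropout_mask(self, mask: np.ndarray) -> "Tensor":
        """Multiply by a pre-drawn (already inverse-scaled) dropout mask."""
        return self * Tensor(mask)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limits
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
                eps: float) -> Tensor:
    """Fused normalize-and-affine: ``(x - mu) / sqrt(var + eps) * gamma + beta``.

    ``mu``/``var`` are taken over ``axes``; ``gamma``/``beta`` must already be
    shaped to broadcast against ``x``.  Used by both layer norm (last axis)
    and training-mode batch norm (axes 0, 2, 3).
    """
    axes = tuple(axes)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivar
    out = xhat * gamma.data + beta.data
    n = int(np.prod([x.shape[a] for a in axes]))

    def backward(grad, x=x, gamma=gamma, beta=beta, xhat=xhat, ivar=ivar,
                 axes=axes, n=n):
        if beta.requires_grad:
            beta._accum(_unbroadcast(grad, beta.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(grad * xhat, gamma.shape))
        if x.requires_grad:
            dxhat = grad * gamma.data
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            x._accum(ivar * (dxhat - (s1 + xhat * s2) / n))

    return Tensor._make(out, (x, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tuple(tensors), offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(int(lo), int(hi))
                t._accum(grad[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def _im2col_indices(h: int, w: int, kh: int, kw: int):
    """Row/col gather indices for valid-mode stride-1 patches.

    Returns arrays of shape (oh*ow, kh*kw) indexing into (h, w).
    """
    oh, ow = h - kh + 1, w - kw + 1
    i0 = np.repeat(np.arange(oh), ow)
    j0 = np.tile(np.arange(ow), oh)
    ki = np.repeat(np.arange(kh), kw)
    kj = np.tile(np.arange(kw), kh)
    rows = i0[:, None] + ki[None, :]
    cols = j0[:, None] + kj[None, :]
    return rows, cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid-mode stride-1 2-D convolution (cross-correlation).

    ``x``: (B, Cin, H, W); ``weight``: (Cout, Cin, KH, KW); ``bias``: (Cout,).
    Returns (B, Cout, H-KH+1, W-KW+1).  Implemented via im2col so that both
    directions reduce to matrix products; the input gradient is a scatter-add
    over the same gather indices.
    """
    b_sz, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin_w != cin:
        raise ValueError(f"weight expects {cin_w} input channels, got {cin}")
    if kh > h or kw > w:
        raise ValueError("kernel larger than input")
    rows, cols, oh, ow = _im2col_indices(h, w, kh, kw)
    # (B, Cin, P, K) -> (B, P, Cin*K)
    patches = x.data[:, :, rows, cols]
    xc = patches.transpose(0, 2, 1, 3).reshape(b_sz, oh * ow, cin * kh * kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = xc @ wmat.T + bias.data  # (B, P, Cout)
    out = out.transpose(0, 2, 1).reshape(b_sz, cout, oh, ow)

    flat_idx = (np.arange(cin)[:, None, None] * (h * w) + rows[None] * w + cols[None])
    # (Cin, P, K) -> (P, Cin*K), matching xc's column order
    flat_idx = flat_idx.transpose(1, 0, 2).reshape(oh * ow, cin * kh * kw)

    def backward(grad, x=x, weight=weight, bias=bias, xc=xc, wmat=wmat,
                 flat_idx=flat_idx, dims=(b_sz, cin, h, w, cout, oh, ow, kh, kw)):
        b_sz, cin, h, w, cout, oh, ow, kh, kw = dims
        g = grad.reshape(b_sz, cout, oh * ow).transpose(0, 2, 1)  # (B, P, Cout)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = g.reshape(-1, cout).T @ xc.reshape(-1, xc.shape[-1])
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gxc = g @ wmat  # (B, P, Cin*K)
            gx = np.zeros((b_sz, cin * h * w))
            np.add.at(gx, (np.arange(b_sz)[:, None, None], flat_idx[None]), gxc.reshape(b_sz, oh * ow, -1))
            x._accum(gx.reshape(b_sz, cin, h, w))

    return Tensor._make(out, (x, weight, bias), backward)
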