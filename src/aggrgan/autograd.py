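"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine exists to train the three base GANs and to supply analytic
gradients for the style-transfer objective on a plain CPU stack.  It is a
tape-based design: every operation on :class:`Tensor` records its parents and
a vector-Jacobian closure; :func:`grad` and :meth:`Tensor.backward` replay the
tape in reverse topological order.

Backward closures are themselves written in Tensor ops, so calling
:func:`grad` with ``create_graph=True`` yields gradients that carry their own
tape.  That is what the Wasserstein-divergence gradient penalty needs: the
critic-input gradient is differentiated a second time with respect to the
critic parameters.  Dense/elementwise ops support this double backprop; the
convolution ops compute their backward in raw numpy and therefore support
first derivatives only (sufficient for the DCGAN losses and for style
transfer, which differentiate convolutions once).

Everything runs in float64 for reproducibility of the seeded training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "grad",
    "add", "sub", "neg", "mul", "div", "powt", "matmul", "transpose",
    "exp", "log", "tanh", "sigmoid", "leaky_relu", "relu", "sqrt",
    "tsum", "tmean", "reshape", "broadcast_to", "getitem",
    "conv2d", "conv_transpose2d", "upsample_nearest", "avg_pool2d",
    "flip_hw", "swap01", "zero_insert",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None  # numpy array, filled by backward()
        self._parents: tuple = ()
        self._vjp = None

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, s):
        return powt(self, s)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    # -- backward ---------------------------------------------------------
    def backward(self, create_graph: bool = False) -> None:
        """Accumulate d(self)/d(leaf) into ``leaf.grad`` for every
        requires-grad leaf reachable from this (scalar) tensor.

        Unless ``create_graph`` is set, the tape is torn down afterwards:
        vjp closures hold reference cycles (node -> closure -> node), and
        releasing them eagerly keeps long training loops flat in memory.
        """
        topo = _topo(self)
        gmap = _backprop(self, create_graph=create_graph)
        for node, g in gmap.items():
            if node._vjp is None and node.requires_grad:
                if node.grad is None:
                    node.grad = g.data.copy()
                else:
                    node.grad = node.grad + g.data
        if not create_graph:
            for node in topo:
                node._parents = ()
                node._vjp = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables taping (forward passes only)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


def _make(data, parents, vjp) -> Tensor:
    req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _topo(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # parents precede consumers


def _backprop(output: Tensor, create_graph: bool):
    """Run the reverse sweep from ``output``; return {node: grad Tensor} for
    every node in the graph (leaves included)."""
    gmap: dict = {id(output): (output, Tensor(np.ones_like(output.data)))}
    for node in reversed(_topo(output)):
        entry = gmap.get(id(node))
        if entry is None:
            continue
        g = entry[1]
        if not create_graph:
            g = Tensor(g.data)  # sever the tape: saves memory
            gmap[id(node)] = (node, g)
        if node._vjp is None:
            continue
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None:
                continue
            prev = gmap.get(id(p))
            gmap[id(p)] = (p, pg) if prev is None else (p, prev[1] + pg)
    return {node: g for node, g in gmap.values()}


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Return d(output)/d(input) for each input, as Tensors.

    With ``create_graph=True`` the returned gradients carry a tape and can be
    differentiated again (dense/elementwise ops only).
    """
    gmap = _backprop(output, create_graph=create_graph)
    out = []
    for t in inputs:
        g = gmap.get(t)
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out


# ---------------------------------------------------------------------------
# broadcasting helper
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` (graph-capable)."""
    if g.data.shape == shape:
        return g
    nd = g.data.ndim - len(shape)
    axes = tuple(range(nd)) + tuple(
        i + nd for i, s in enumerate(shape) if s == 1 and g.data.shape[i + nd] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data, (a, b),
        lambda g: (_sum_to(g, a.data.shape), _sum_to(g, b.data.shape)),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data, (a, b),
        lambda g: (_sum_to(mul(g, b), a.data.shape), _sum_to(mul(g, a), b.data.shape)),
    )


def powt(a, s: float) -> Tensor:
    a = as_tensor(a)
    s = float(s)
    return _make(
        a.data ** s, (a,),
        lambda g: (mul(g, mul(powt(a, s - 1.0), Tensor(s))),),
    )


def div(a, b) -> Tensor:
    return mul(as_tensor(a), powt(as_tensor(b), -1.0))


def sqrt(a) -> Tensor:
    return powt(a, 0.5)


def transpose(a) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.T, (a,), lambda g: (transpose(g),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data @ b.data, (a, b),
        lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (div(g, a),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    x = a.data
    data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = _make(data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope)
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.data.shape),))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(
        np.broadcast_to(a.data, shape).copy(), (a,),
        lambda g: (_sum_to(g, a.data.shape),),
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            gk = reshape(g, (1,) * a.data.ndim)
        elif keepdims:
            gk = g
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            ks = tuple(1 if i in axes else s for i, s in enumerate(a.data.shape))
            gk = reshape(g, ks)
        return (broadcast_to(gk, a.data.shape),)

    return _make(data, (a,), vjp)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def getitem(a, idx) -> Tensor:
    """Basic/advanced indexing; backward is first-order only (scatter-add)."""
    a = as_tensor(a)

    def vjp(g):
        z = np.zeros_like(a.data)
        np.add.at(z, idx, g.data)
        return (Tensor(z),)

    return _make(a.data[idx], (a,), vjp)


def flip_hw(a) -> Tensor:
    a = as_tensor(a)
    return _make(a.data[..., ::-1, ::-1].copy(), (a,), lambda g: (flip_hw(g),))


def swap01(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.swapaxes(a.data, 0, 1).copy(), (a,), lambda g: (swap01(g),))


def zero_insert(a, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between pixels along H and W (NCHW)."""
    a = as_tensor(a)
    n, c, h, w = a.data.shape
    out = np.zeros((n, c, stride * (h - 1) + 1, stride * (w - 1) + 1))
    out[:, :, ::stride, ::stride] = a.data
    return _make(out, (a,), lambda g: (getitem(g, np.s_[:, :, ::stride, ::stride]),))


# ---------------------------------------------------------------------------
# convolution family (first-order backward, raw numpy inside)
# ---------------------------------------------------------------------------

def _normalize_pad(pad):
    if isinstance(pad, int):
        return ((pad, pad), (pad, pad))
    (pt, pb), (pl, pr) = pad
    return ((pt, pb), (pl, pr))


def conv2d(x, w, b=None, stride: int = 1, pad=0) -> Tensor:
    """2-D cross-correlation, NCHW input, (Cout, Cin, kh, kw) weights.

    Computed as a sum of per-kernel-offset tensor contractions; nothing
    larger than the activations themselves is ever materialized.
    """
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
    (pt, pb), (pl, pr) = _normalize_pad(pad)
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    oh = (h + pt + pb - kh) // stride + 1
    ow = (wd + pl + pr - kw) // stride + 1
    out = np.zeros((n, cout, oh, ow))
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            out += np.tensordot(w.data[:, :, i, j], xs,
                                axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    def vjp(g):
        gd = g.data
        dw = np.empty_like(w.data) if w.requires_grad else None
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if dw is not None:
                    xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
                    dw[:, :, i, j] = np.tensordot(gd, xs, axes=([0, 2, 3], [0, 2, 3]))
                if dxp is not None:
                    dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                        np.tensordot(w.data[:, :, i, j], gd,
                                     axes=([0], [1])).transpose(1, 0, 2, 3)
        grads = [Tensor(dxp[:, :, pt:pt + h, pl:pl + wd]) if dxp is not None else None,
                 Tensor(dw) if dw is not None else None]
        if b is not None:
            grads.append(Tensor(gd.sum(axis=(0, 2, 3))) if b.requires_grad else None)
        return tuple(grads)

    return _make(out, parents, vjp)


def conv_transpose2d(x, w, b=None, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; weights shaped (Cin, Cout, kh, kw).

    Implemented as zero-insertion upsampling followed by a stride-1
    convolution with the spatially flipped, axis-swapped kernel; output size
    is ``stride*(H-1) + kh - 2*pad``.
    """
    x, w = as_tensor(x), as_tensor(w)
    kh = w.data.shape[2]
    xs = zero_insert(x, stride) if stride > 1 else x
    return conv2d(xs, swap01(flip_hw(w)), b=b, stride=1, pad=kh - 1 - pad)


def upsample_nearest(x, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def vjp(g):
        gr = g.data.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        return (Tensor(gr),)

    return _make(out, (x,), vjp)


def avg_pool2d(x, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial size {(h, w)} not divisible by {k}")
    out = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def vjp(g):
        gr = np.repeat(np.repeat(g.data, k, axis=2), k, axis=3) / (k * k)
        return (Tensor(gr),)

    return _make(out, (x,), vjp)
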