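"""Minimal reverse-mode automatic differentiation on numpy arrays.

The adversarial training objective used for mask generation contains a
gradient penalty: the critic loss depends on the norm of the critic's
gradient with respect to its input, and updating the critic therefore
requires differentiating *through* that gradient (a second-order term).
To support this, every primitive's vector-Jacobian product (vjp) is itself
written with engine primitives, so calling :func:`grad` with
``create_graph=True`` yields gradient tensors that carry their own graph
and can be differentiated again.

Only the small set of primitives needed by the package's networks is
provided: broadcast arithmetic, matmul, reshape/transpose/slice, gather and
scatter-add along a flattened axis (the backbone of im2col convolutions),
max-reduction (pooling), and the pointwise nonlinearities.
"""

from __future__ import annotations

from contextlib import contextmanager, nullcontext

import numpy as np

_GRAD_MODE = [True]


@contextmanager
def no_grad():
    """Disable graph construction inside the block (pure numpy speed)."""
    _GRAD_MODE.append(False)
    try:
        yield
    finally:
        _GRAD_MODE.pop()


def _tracing() -> bool:
    return _GRAD_MODE[-1]


class Tensor:
    """A numpy array plus the tape metadata needed for reverse mode."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _tracing()
        self._parents: tuple = ()
        self._vjp = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other, self.dtype)))

    def __rsub__(self, other):
        return add(astensor(other, self.dtype), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(astensor(other, self.dtype), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other, self.dtype), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return slice_(self, key)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def astensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.number):
        arr = arr.astype(dtype)
    return Tensor(arr)


def _node(data: np.ndarray, parents, vjp) -> Tensor:
    """Create an output tensor, attaching tape metadata when tracing."""
    out = Tensor(data)
    if _tracing() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


# ----------------------------------------------------------------------
# backward pass
# ----------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, wrt, create_graph: bool = False):
    """Gradients of a scalar ``output`` with respect to each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients are themselves
    differentiable (needed for the gradient-penalty parameter update).
    Branches of the graph that cannot reach any ``wrt`` tensor are skipped,
    and each vjp receives a per-parent needs mask so expensive co-gradients
    (e.g. the second matmul operand) are not computed when unused.
    """
    if output.size != 1:
        raise ValueError("grad() expects a scalar output")
    topo = _toposort(output)
    wrt_ids = {id(w) for w in wrt}
    need: dict[int, bool] = {}
    for node in topo:  # ancestors first
        need[id(node)] = id(node) in wrt_ids or any(
            need.get(id(p), False) for p in node._parents
        )
    grads = {id(output): Tensor(np.ones_like(output.data))}
    ctx = nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            needs = tuple(
                p.requires_grad and need.get(id(p), False) for p in node._parents
            )
            if not any(needs):
                continue
            for p, pg, needed in zip(node._parents, node._vjp(g, needs), needs):
                if pg is None or not needed:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else add(acc, pg)
    out = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        out.append(g)
    return out


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1
    )
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = _node(a.data + b.data, (a, b), None)
    if out.requires_grad:
        def vjp(g, needs=(True, True)):
            return (
                _unbroadcast(g, a.shape) if needs[0] else None,
                _unbroadcast(g, b.shape) if needs[1] else None,
            )
        out._vjp = vjp
    return out


def neg(a) -> Tensor:
    a = astensor(a)
    out = _node(-a.data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (neg(g),)
    return out


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = _node(a.data * b.data, (a, b), None)
    if out.requires_grad:
        def vjp(g, needs=(True, True)):
            return (
                _unbroadcast(mul(g, b), a.shape) if needs[0] else None,
                _unbroadcast(mul(g, a), b.shape) if needs[1] else None,
            )
        out._vjp = vjp
    return out


def pow_(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)
    out = _node(a.data ** p, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, mul(astensor(np.asarray(p, a.dtype)), pow_(a, p - 1.0))),)
    return out


def log(a) -> Tensor:
    a = astensor(a)
    out = _node(np.log(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, pow_(a, -1.0)),)
    return out


def exp(a) -> Tensor:
    a = astensor(a)
    out = _node(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, out),)
    return out


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def _mm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matmul with a single-gemm fast path for batched-3D @ 2D operands."""
    if a.ndim == 3 and b.ndim == 2 and a.flags.c_contiguous:
        bsz, m, k = a.shape
        return (a.reshape(bsz * m, k) @ b).reshape(bsz, m, b.shape[1])
    return np.matmul(a, b)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires ndim >= 2 operands")
    out = _node(_mm(a.data, b.data), (a, b), None)
    if out.requires_grad:
        def vjp(g, needs=(True, True)):
            ga = gb = None
            if needs[0]:
                if a.ndim == 2 and g.ndim == 3:
                    ga = matmul_contract(g, transpose_last(b))
                else:
                    ga = _unbroadcast(matmul(g, transpose_last(b)), a.shape)
            if needs[1]:
                if b.ndim == 2 and g.ndim == 3:
                    gb = matmul_contract(transpose_last(a), g)
                else:
                    gb = _unbroadcast(matmul(transpose_last(a), g), b.shape)
            return ga, gb
        out._vjp = vjp
    return out


def matmul_contract(a, b) -> Tensor:
    """Batch-summed matmul: sum_b a[b] @ b[b], as one gemm.

    The adjoint-of-broadcast pattern in conv weight gradients; kept as a
    primitive so the sum over the batch is fused instead of materialized.
    """
    a, b = astensor(a), astensor(b)
    ad_, bd = a.data, b.data
    data = np.zeros((ad_.shape[1], bd.shape[2]), dtype=np.result_type(ad_, bd))
    for i in range(ad_.shape[0]):  # per-sample gemms avoid giant transposes
        data += ad_[i] @ bd[i]
    out = _node(data, (a, b), None)
    if out.requires_grad:
        def vjp(g, needs=(True, True)):
            ga = matmul(g, transpose_last(b)) if needs[0] else None
            gb = matmul(transpose_last(a), g) if needs[1] else None
            return ga, gb
        out._vjp = vjp
    return out


def transpose_last(a) -> Tensor:
    """Swap the last two axes."""
    a = astensor(a)
    perm = list(range(a.ndim))
    perm[-1], perm[-2] = perm[-2], perm[-1]
    return transpose(a, perm)


def transpose(a, perm) -> Tensor:
    a = astensor(a)
    perm = tuple(perm)
    out = _node(np.transpose(a.data, perm), (a,), None)
    if out.requires_grad:
        inv = tuple(np.argsort(perm))
        out._vjp = lambda g, needs=None: (transpose(g, inv),)
    return out


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = _node(np.reshape(a.data, shape), (a,), None)
    if out.requires_grad:
        orig = a.shape
        out._vjp = lambda g, needs=None: (reshape(g, orig),)
    return out


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = _node(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), None)
    if out.requires_grad:
        shape = a.shape

        def vjp(g, needs=None):
            gk = g
            if not keepdims and axis is not None:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                kshape = list(shape)
                for ax in axes:
                    kshape[ax] = 1
                gk = reshape(g, tuple(kshape))
            elif not keepdims and axis is None:
                gk = reshape(g, (1,) * len(shape))
            return (broadcast_to(gk, shape),)

        out._vjp = vjp
    return out


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), astensor(np.asarray(1.0 / n, a.dtype)))


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    # read-only broadcast view; every consumer only reads
    out = _node(np.broadcast_to(a.data, shape), (a,), None)
    if out.requires_grad:
        orig = a.shape
        out._vjp = lambda g, needs=None: (_unbroadcast(g, orig),)
    return out


def reduce_max(a, axis, keepdims=False) -> Tensor:
    """Max over ``axis``; gradient splits evenly across ties."""
    a = astensor(a)
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    mx = np.max(a.data, axis=axes, keepdims=True)
    data = mx if keepdims else np.squeeze(mx, axis=axes)
    out = _node(data, (a,), None)
    if out.requires_grad:
        w = (a.data == mx).astype(a.dtype)
        w /= w.sum(axis=axes, keepdims=True, dtype=a.dtype)
        shape = a.shape
        kshape = mx.shape

        def vjp(g, needs=None):
            gk = g if keepdims else reshape(g, kshape)
            return (mul(broadcast_to(gk, shape), astensor(w)),)

        out._vjp = vjp
    return out


def slice_(a, key) -> Tensor:
    a = astensor(a)
    out = _node(a.data[key], (a,), None)
    if out.requires_grad:
        shape = a.shape
        out._vjp = lambda g, needs=None: (unslice(g, key, shape),)
    return out


def unslice(a, key, shape) -> Tensor:
    """Embed ``a`` into zeros of ``shape`` at ``key`` (adjoint of slicing)."""
    a = astensor(a)
    buf = np.zeros(shape, dtype=a.dtype)
    buf[key] = a.data
    out = _node(buf, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (slice_(g, key),)
    return out


def pad_zeros(a, pad_width) -> Tensor:
    """Constant zero padding, expressed through :func:`unslice`."""
    a = astensor(a)
    shape = tuple(s + lo + hi for s, (lo, hi) in zip(a.shape, pad_width))
    key = tuple(slice(lo, lo + s) for s, (lo, _) in zip(a.shape, pad_width))
    return unslice(a, key, shape)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        ndim = tensors[0].ndim
        ax = axis % ndim

        def vjp(g, needs=None):
            if needs is None:
                needs = (True,) * len(sizes)
            gs, start = [], 0
            for s, needed in zip(sizes, needs):
                key = tuple(
                    slice(start, start + s) if i == ax else slice(None)
                    for i in range(ndim)
                )
                gs.append(slice_(g, key) if needed else None)
                start += s
            return tuple(gs)

        out._vjp = vjp
    return out


def take_flat(a, idx) -> Tensor:
    """Gather along the last axis: ``out[..., *idx.shape] = a[..., idx]``.

    ``idx`` is an integer array or a :class:`GatherPlan`.
    """
    a = astensor(a)
    if isinstance(idx, GatherPlan):
        data = idx.take(a.data)
    else:
        data = np.take(a.data, idx, axis=-1)
    out = _node(data, (a,), None)
    if out.requires_grad:
        size = a.shape[-1]
        out._vjp = lambda g, needs=None: (scatter_flat(g, idx, size),)
    return out


class GatherPlan:
    """Regular patch gather/scatter between a padded grid and a block grid.

    Describes the im2col correspondence: for each of K kernel offsets, the
    patch elements form a strided block of the flattened source grid. Both
    directions are then pure slice copies / slice adds, with no index
    arrays, which is substantially faster than generic fancy indexing.

    Equivalent to an integer index array of shape (K, L) into a flattened
    last axis of ``prod(grid_dims)``.
    """

    def __init__(self, grid_dims, block_dims, offsets, stride: int):
        self.grid_dims = tuple(int(n) for n in grid_dims)
        self.block_dims = tuple(int(n) for n in block_dims)
        self.offsets = [tuple(int(o) for o in off) for off in offsets]
        self.stride = int(stride)
        self.shape = (len(self.offsets), int(np.prod(self.block_dims)))
        self.size = int(np.prod(self.grid_dims))
        self._idx = None

    @property
    def idx(self) -> np.ndarray:
        """Equivalent flat (K, L) index array (built lazily, cached)."""
        if self._idx is None:
            strides = np.cumprod((1,) + self.grid_dims[::-1][:-1])[::-1]
            grids = np.meshgrid(
                *[np.arange(n) * self.stride for n in self.block_dims], indexing="ij"
            )
            base = sum(g.ravel() * s for g, s in zip(grids, strides))
            off = np.array([sum(o * s for o, s in zip(ofs, strides)) for ofs in self.offsets])
            self._idx = (off[:, None] + base[None, :]).astype(np.intp)
        return self._idx

    def _key(self, off):
        return tuple(
            slice(o, o + self.stride * (n - 1) + 1, self.stride)
            for o, n in zip(off, self.block_dims)
        )

    def take(self, x: np.ndarray) -> np.ndarray:
        return np.take(x, self.idx, axis=-1)

    def scatter(self, v: np.ndarray) -> np.ndarray:
        lead = v.shape[: v.ndim - 2]
        buf = np.zeros(lead + self.grid_dims, dtype=v.dtype)
        for k, off in enumerate(self.offsets):
            blk = v[(Ellipsis, k, slice(None))].reshape(lead + self.block_dims)
            buf[(Ellipsis,) + self._key(off)] += blk
        return buf.reshape(lead + (self.size,))


def scatter_flat(a, idx, size: int) -> Tensor:
    """Adjoint of :func:`take_flat`: scatter-add into a last axis of ``size``."""
    a = astensor(a)
    kl = idx.shape
    lead = a.shape[: a.ndim - 2]
    if a.shape[a.ndim - 2:] != kl:
        raise ValueError("trailing dims of input must equal the plan shape")
    if isinstance(idx, GatherPlan):
        if size != idx.size:
            raise ValueError("size does not match plan")
        buf = idx.scatter(a.data)
    else:
        flat = a.data.reshape(-1, int(np.prod(kl)))
        buf = np.zeros((flat.shape[0], size), dtype=a.dtype)
        idxf = np.ravel(idx)
        for m in range(flat.shape[0]):
            buf[m] = np.bincount(idxf, weights=flat[m], minlength=size)
        buf = buf.reshape(lead + (size,))
    out = _node(buf.reshape(lead + (size,)), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (take_flat(g, idx),)
    return out


def sigmoid(a) -> Tensor:
    a = astensor(a)
    x = a.data
    y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)
    out = _node(y, (a,), None)
    if out.requires_grad:
        one = astensor(np.asarray(1.0, a.dtype))
        out._vjp = lambda g, needs=None: (mul(g, mul(out, add(one, neg(out)))),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    one = a.dtype.type(1.0) if hasattr(a.dtype, "type") else 1.0
    m = np.where(a.data > 0, one, a.dtype.type(slope))
    out = _node(a.data * m, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, astensor(m)),)
    return out


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed only where unclipped."""
    a = astensor(a)
    m = ((a.data > lo) & (a.data < hi)).astype(a.dtype)
    out = _node(np.clip(a.data, lo, hi), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, astensor(m)),)
    return out


def abs_(a) -> Tensor:
    a = astensor(a)
    s = np.sign(a.data).astype(a.dtype)
    out = _node(np.abs(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g, needs=None: (mul(g, astensor(s)),)
    return out
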