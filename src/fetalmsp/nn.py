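"""Neural-network layers and optimizers on top of the autodiff engine.

Convolutions are im2col gathers followed by a matmul; transposed
convolutions are a matmul followed by the adjoint scatter (col2im). Both
directions therefore differentiate to arbitrary order, which the critic's
gradient-penalty update relies on.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


# ----------------------------------------------------------------------
# im2col index plumbing (cached: index arrays depend only on geometry)
# ----------------------------------------------------------------------

_IDX_CACHE: dict = {}


def _conv_out_size(n: int, k: int, stride: int, dilation: int) -> int:
    eff = (k - 1) * dilation + 1
    return (n - eff) // stride + 1


def _patch_plan(dims, k: int, stride: int, dilation: int) -> ad.GatherPlan:
    """im2col plan: patches of a (padded) ``dims`` grid, shape (k^nd, L)."""
    key = (tuple(dims), k, stride, dilation)
    hit = _IDX_CACHE.get(key)
    if hit is not None:
        return hit
    from itertools import product

    out_dims = [_conv_out_size(n, k, stride, dilation) for n in dims]
    offsets = [tuple(o * dilation for o in off) for off in product(range(k), repeat=len(dims))]
    plan = ad.GatherPlan(dims, out_dims, offsets, stride)
    _IDX_CACHE[key] = plan
    return plan


def _scatter_plan(in_dims, out_dims_padded, k: int, stride: int) -> ad.GatherPlan:
    """col2im plan: kernel-offset blocks of a padded output grid, (k^nd, L_in)."""
    key = ("t", tuple(in_dims), tuple(out_dims_padded), k, stride)
    hit = _IDX_CACHE.get(key)
    if hit is not None:
        return hit
    from itertools import product

    offsets = list(product(range(k), repeat=len(in_dims)))
    plan = ad.GatherPlan(out_dims_padded, in_dims, offsets, stride)
    _IDX_CACHE[key] = plan
    return plan


# ----------------------------------------------------------------------
# modules
# ----------------------------------------------------------------------

class Module:
    """Base class: parameter bookkeeping and a state dict for checkpoints."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def state_dict(self) -> list[np.ndarray]:
        out = [
            v.data.copy()
            for v in self.__dict__.values()
            if isinstance(v, Tensor) and v.requires_grad
        ]
        for child in self._children():
            out.extend(child.state_dict())
        return out

    def load_state_dict(self, state) -> None:
        state = list(state)
        if len(state) != len(self.state_dict()):
            raise ValueError("state dict does not match module")
        self._load(iter(state))

    def _load(self, it) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.array(next(it), dtype=v.data.dtype)
        for child in self._children():
            if type(child).state_dict is not Module.state_dict:
                # modules with custom buffers load their own entries
                n = len(child.state_dict())
                child.load_state_dict([next(it) for _ in range(n)])
            else:
                child._load(it)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)
    return Tensor(w, requires_grad=True)


class ConvNd(Module):
    """N-dimensional convolution (nd inferred from the input)."""

    def __init__(self, rng, in_ch: int, out_ch: int, k: int, nd: int,
                 stride: int = 1, dilation: int = 1, pad: int | None = None):
        self.in_ch, self.out_ch, self.k, self.nd = in_ch, out_ch, k, nd
        self.stride, self.dilation = stride, dilation
        if pad is None:
            total = (k - 1) * dilation if stride == 1 else max((k - 1) * dilation + 1 - stride, 0)
            self.pad = (total // 2, total - total // 2)
        elif isinstance(pad, tuple):
            self.pad = pad
        else:
            self.pad = (int(pad), int(pad))
        fan_in = in_ch * k ** nd
        self.weight = _he_init(rng, (out_ch, fan_in), fan_in)
        self.bias = Tensor(np.zeros((out_ch, 1), dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        nd, (plo, phi) = self.nd, self.pad
        spatial = x.shape[2:]
        if len(spatial) != nd:
            raise ValueError(f"expected {nd}D input, got shape {x.shape}")
        if plo or phi:
            x = ad.pad_zeros(x, ((0, 0), (0, 0)) + ((plo, phi),) * nd)
        pdims = x.shape[2:]
        b, c = x.shape[0], x.shape[1]
        idx = _patch_plan(pdims, self.k, self.stride, self.dilation)
        xf = ad.reshape(x, (b, c, int(np.prod(pdims))))
        col = ad.take_flat(xf, idx)                      # (B, C, K, L)
        col = ad.reshape(col, (b, c * idx.shape[0], idx.shape[1]))
        out = ad.matmul(self.weight, col)                # (B, out_ch, L)
        out = ad.add(out, self.bias)
        odims = tuple(_conv_out_size(n, self.k, self.stride, self.dilation) for n in pdims)
        return ad.reshape(out, (b, self.out_ch) + odims)


class Conv2d(ConvNd):
    def __init__(self, rng, in_ch, out_ch, k, **kw):
        super().__init__(rng, in_ch, out_ch, k, nd=2, **kw)


class Conv3d(ConvNd):
    def __init__(self, rng, in_ch, out_ch, k, **kw):
        super().__init__(rng, in_ch, out_ch, k, nd=3, **kw)


class ConvTransposeNd(Module):
    """Transposed convolution: out = (in-1)*stride + k - 2*pad."""

    def __init__(self, rng, in_ch: int, out_ch: int, k: int, nd: int,
                 stride: int = 2, pad: int | None = None):
        self.in_ch, self.out_ch, self.k, self.nd = in_ch, out_ch, k, nd
        self.stride = stride
        self.pad = pad if pad is not None else max((k - stride) // 2, 0)
        fan_in = in_ch
        self.weight = _he_init(rng, (out_ch * k ** nd, in_ch), fan_in * k ** nd)
        self.bias = Tensor(
            np.zeros((out_ch,) + (1,) * nd, dtype=DTYPE), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        nd, k, s, p = self.nd, self.k, self.stride, self.pad
        b, c = x.shape[0], x.shape[1]
        in_dims = x.shape[2:]
        out_dims = tuple((n - 1) * s + k - 2 * p for n in in_dims)
        padded = tuple(o + 2 * p for o in out_dims)
        idx = _scatter_plan(in_dims, padded, k, s)       # (K, L_in)
        xf = ad.reshape(x, (b, c, int(np.prod(in_dims))))
        col = ad.matmul(self.weight, xf)                 # (B, out_ch*K, L_in)
        col = ad.reshape(col, (b, self.out_ch, k ** nd, idx.shape[1]))
        out = ad.scatter_flat(col, idx, int(np.prod(padded)))
        out = ad.reshape(out, (b, self.out_ch) + padded)
        if p:
            key = (slice(None), slice(None)) + tuple(slice(p, p + o) for o in out_dims)
            out = ad.slice_(out, key)
        return ad.add(out, ad.reshape(self.bias, (self.out_ch,) + (1,) * nd))


class ConvTranspose2d(ConvTransposeNd):
    def __init__(self, rng, in_ch, out_ch, k, **kw):
        super().__init__(rng, in_ch, out_ch, k, nd=2, **kw)


class ConvTranspose3d(ConvTransposeNd):
    def __init__(self, rng, in_ch, out_ch, k, **kw):
        super().__init__(rng, in_ch, out_ch, k, nd=3, **kw)


class BatchNorm(Module):
    """Per-channel batch normalization for (B, C, *spatial) tensors.

    Batch statistics during training, running averages at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((channels,), dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((channels,), dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros((channels,), dtype=DTYPE)
        self.running_var = np.ones((channels,), dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        c = x.shape[1]
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, c) + (1,) * (x.ndim - 2)
        if training:
            mu = ad.mean_(x, axis=axes, keepdims=True)
            xc = ad.add(x, ad.neg(mu))
            var = ad.mean_(ad.mul(xc, xc), axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = ad.astensor(self.running_mean.reshape(bshape))
            xc = ad.add(x, ad.neg(mu))
            var = ad.astensor(self.running_var.reshape(bshape))
        inv = ad.pow_(ad.add(var, ad.astensor(np.asarray(self.eps, DTYPE))), -0.5)
        norm = ad.mul(xc, inv)
        return ad.add(ad.mul(norm, ad.reshape(self.gamma, bshape)),
                      ad.reshape(self.beta, bshape))

    # running buffers ride along with the weights in checkpoints
    def state_dict(self):
        return [self.gamma.data.copy(), self.beta.data.copy(),
                self.running_mean.copy(), self.running_var.copy()]

    def load_state_dict(self, state):
        self.gamma.data, self.beta.data = state[0], state[1]
        self.running_mean, self.running_var = state[2], state[3]


class Dense(Module):
    def __init__(self, rng, in_f: int, out_f: int):
        self.weight = _he_init(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros((out_f,), dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


def max_pool(x: Tensor, nd: int, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible."""
    b, c = x.shape[0], x.shape[1]
    spatial = x.shape[2:]
    if any(n % factor for n in spatial):
        raise ValueError(f"spatial dims {spatial} not divisible by {factor}")
    newshape = (b, c)
    for n in spatial:
        newshape += (n // factor, factor)
    x = ad.reshape(x, newshape)
    axes = tuple(3 + 2 * i for i in range(nd))
    out = ad.reduce_max(x, axis=axes)
    return out


def max_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    return max_pool(x, 2, factor)


def max_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    return max_pool(x, 3, factor)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

EPS = 1e-7


def binary_cross_entropy(pred: Tensor, target: Tensor) -> Tensor:
    """Mean of -t*log(p) - (1-t)*log(1-p), with p clipped to [eps, 1-eps]."""
    p = ad.clip(pred, EPS, 1.0 - EPS)
    t = ad.astensor(target, pred.dtype)
    one = ad.astensor(np.asarray(1.0, p.dtype))
    loss = ad.neg(ad.add(ad.mul(t, ad.log(p)),
                         ad.mul(ad.add(one, ad.neg(t)), ad.log(ad.add(one, ad.neg(p))))))
    return ad.mean_(loss)


def huber(pred: Tensor, target: Tensor, delta: float = 1.0) -> Tensor:
    """Mean Huber loss (quadratic within ``delta``, linear outside)."""
    r = ad.add(pred, ad.neg(ad.astensor(target, pred.dtype)))
    a = ad.abs_(r)
    small = (a.data <= delta).astype(pred.dtype)
    quad = ad.mul(ad.astensor(np.asarray(0.5, pred.dtype)), ad.mul(r, r))
    lin = ad.mul(ad.astensor(np.asarray(delta, pred.dtype)),
                 ad.add(a, ad.astensor(np.asarray(-0.5 * delta, pred.dtype))))
    mixed = ad.add(ad.mul(ad.astensor(small), quad),
                   ad.mul(ad.astensor(1.0 - small), lin))
    return ad.mean_(mixed)


# ----------------------------------------------------------------------
# optimizers
# ----------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2, momentum=0.9, weight_decay=5e-4):
        self.params = list(params)
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads) -> None:
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else g
            gd = gd + self.wd * p.data
            self.v[i] = self.mu * self.v[i] - self.lr * gd
            p.data = p.data + self.v[i]
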