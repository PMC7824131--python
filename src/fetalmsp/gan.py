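"""Adversarial mask generation: 3D generator, critic, and WGAN-GP training.

The generator is a symmetric 3D autoencoder mapping a cropped volume to a
soft plane mask of the same size (sigmoid output). The critic scores
two-channel combined inputs (mask * volume, volume) and outputs a latent
vector rather than a scalar; expectations over the critic in the losses
reduce that vector by its mean.

Losses, with w the cross-entropy/adversarial tradeoff and lambda the
gradient-penalty weight:

    L_G = -(1 - w) E[C(x')] + w L_ce
    L_C =  E[C(x')] - E[C(y')] + lambda E[(||grad_{x_hat'} C(x_hat')||_2 - 1)^2]

where x is the predicted mask, y the ground truth, x_hat = alpha y +
(1 - alpha) x with per-sample alpha ~ U(0, 1), and primes denote the
two-channel combination with the input volume. The critic and generator are
updated alternately (one step each) with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass(frozen=True)
class GeneratorConfig:
    """Symmetric autoencoder: 4 strided conv encoder layers, 2 dense latent
    layers, 4 transposed-conv decoder layers, sigmoid output."""

    encoder_channels: tuple[int, int, int, int] = (16, 32, 64, 64)
    latent: int = 200
    kernel: int = 4
    leaky_slope: float = 0.2


@dataclass(frozen=True)
class CriticConfig:
    """4 stride-1 conv layers, each followed by 2x max-pooling; latent output."""

    channels: tuple[int, int, int, int] = (16, 32, 64, 64)
    kernel: int = 3
    leaky_slope: float = 0.2
    latent_dim: int = 64


@dataclass(frozen=True)
class LossWeights:
    w: float = 0.8
    lam: float = 10.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")


def scaled_generator_config() -> GeneratorConfig:
    """Narrow configuration for 32-cube volumes trained on one CPU."""
    return GeneratorConfig(encoder_channels=(8, 16, 32, 32), latent=128)


def scaled_critic_config() -> CriticConfig:
    return CriticConfig(channels=(8, 16, 32, 32), latent_dim=32)


# ----------------------------------------------------------------------
# combination operation
# ----------------------------------------------------------------------

def combine(mask, volume):
    """Two-channel combined input: (mask * volume, volume).

    Channel 1 is the elementwise product (the masked intensity plane),
    channel 2 the unchanged volume. Accepts numpy arrays (returns an array
    with a leading channel axis of size 2 after the batch axis) or engine
    tensors shaped (B, 1, D, H, W) (returns a (B, 2, D, H, W) tensor inside
    the training graph).
    """
    if isinstance(mask, Tensor) or isinstance(volume, Tensor):
        m, v = ad.astensor(mask), ad.astensor(volume)
        if m.shape != v.shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {v.shape}")
        return ad.concat([ad.mul(m, v), v], axis=1)
    m, v = np.asarray(mask), np.asarray(volume)
    if m.shape != v.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {v.shape}")
    if not (np.isfinite(m).all() and np.isfinite(v).all()):
        raise ValueError("inputs must be finite")
    return np.stack([m * v, v], axis=0)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def cross_entropy(x, y):
    """Mean voxelwise cross-entropy E[-y log x - (1-y) log(1-x)].

    x is a soft mask in [0, 1] (clipped to [1e-7, 1 - 1e-7]); y is binary.
    Returns a float for array inputs, a graph tensor for tensor inputs.
    """
    tensor_in = isinstance(x, Tensor) or isinstance(y, Tensor)
    xt, yt = ad.astensor(x), ad.astensor(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    out = nn.binary_cross_entropy(xt, ad.astensor(yt, xt.dtype))
    return out if tensor_in else float(out.item())


def critic_expectation(critic_out: Tensor) -> Tensor:
    """Reduce the critic's latent output to a scalar: mean over batch and
    latent components (the expectation in the losses)."""
    return ad.mean_(critic_out)


def generator_loss(critic_fake_out, x, y, weights: LossWeights):
    """-(1-w) E[C(x')] + w L_ce."""
    tensor_in = isinstance(x, Tensor)
    adv = critic_expectation(ad.astensor(critic_fake_out))
    ce = cross_entropy(ad.astensor(x), ad.astensor(y))
    w = weights.w
    out = ad.add(ad.mul(ad.astensor(np.asarray(-(1.0 - w), adv.dtype)), adv),
                 ad.mul(ad.astensor(np.asarray(w, ce.dtype)), ce))
    return out if tensor_in or isinstance(critic_fake_out, Tensor) else float(out.item())


def gradient_penalty(critic, x_hat_prime):
    """E over the batch of (||grad of the reduced critic output wrt the
    combined interpolate||_2 - 1)^2.

    The gradient norm per sample runs over both channels and all voxels.
    Returns a tensor that is differentiable with respect to the critic
    parameters (second-order term of the critic loss).
    """
    xh = x_hat_prime if isinstance(x_hat_prime, Tensor) else Tensor(
        np.asarray(x_hat_prime, dtype=nn.DTYPE))
    leaf = Tensor(xh.data, requires_grad=True)
    out = critic(leaf)  # (B, latent)
    # summing the per-sample means gives every sample's own gradient in one pass
    score = ad.mul(ad.sum_(out), ad.astensor(np.asarray(1.0 / out.shape[1], out.dtype)))
    (g,) = ad.grad(score, [leaf], create_graph=True)
    if not np.all(np.isfinite(g.data)):
        raise FloatingPointError("non-finite critic input gradient")
    b = g.shape[0]
    g2 = ad.sum_(ad.reshape(ad.mul(g, g), (b, -1)), axis=1)
    norm = ad.pow_(ad.add(g2, ad.astensor(np.asarray(1e-12, g.dtype))), 0.5)
    dev = ad.add(norm, ad.astensor(np.asarray(-1.0, g.dtype)))
    return ad.mean_(ad.mul(dev, dev))


def critic_loss(critic, x_prime, y_prime, x_hat_prime, weights: LossWeights):
    """E[C(x')] - E[C(y')] + lambda * gradient penalty."""
    xp, yp = ad.astensor(x_prime), ad.astensor(y_prime)
    b = xp.shape[0]
    scores = critic(ad.concat([xp, yp], axis=0))  # one pass over fake + real
    fake = critic_expectation(scores[:b])
    real = critic_expectation(scores[b:])
    loss = ad.add(fake, ad.neg(real))
    if weights.lam != 0.0:
        gp = gradient_penalty(critic, x_hat_prime)
        loss = ad.add(loss, ad.mul(ad.astensor(np.asarray(weights.lam, gp.dtype)), gp))
    return loss


# ----------------------------------------------------------------------
# networks
# ----------------------------------------------------------------------

class Generator(nn.Module):
    """Symmetric 3D autoencoder with a dense bottleneck and sigmoid output."""

    def __init__(self, config: GeneratorConfig, volume_size: int, rng):
        self.config = config
        self.volume_size = int(volume_size)
        k, ch = config.kernel, config.encoder_channels
        if self.volume_size % 16 != 0:
            raise ValueError("volume size must be divisible by 16 (4 stride-2 layers)")
        self.slope = config.leaky_slope
        cin = 1
        self.enc = []
        self.enc_bn = []
        for c in ch:
            self.enc.append(nn.Conv3d(rng, cin, c, k, stride=2, pad=(k - 2) // 2))
            self.enc_bn.append(nn.BatchNorm(c))
            cin = c
        self.bottom = self.volume_size // 16
        flat = ch[-1] * self.bottom**3
        self.fc1 = nn.Dense(rng, flat, config.latent)
        self.fc2 = nn.Dense(rng, config.latent, flat)
        self.dec = []
        self.dec_bn = []
        dec_ch = list(ch[::-1][1:]) + [1]
        cin = ch[-1]
        for c in dec_ch:
            self.dec.append(nn.ConvTranspose3d(rng, cin, c, k, stride=2))
            if c != 1:
                self.dec_bn.append(nn.BatchNorm(c))
            cin = c
        # start the sigmoid output near the sparse-mask base rate
        self.dec[-1].bias.data[...] = -3.2
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.volume_size:
            raise ValueError(
                f"generator trained at size {self.volume_size}, got {x.shape[2:]}"
            )
        h = x
        for conv, bn in zip(self.enc, self.enc_bn):
            h = ad.leaky_relu(bn(conv(h), training=self.training), self.slope)
        b = h.shape[0]
        h = ad.reshape(h, (b, -1))
        h = ad.leaky_relu(self.fc1(h), self.slope)
        h = ad.leaky_relu(self.fc2(h), self.slope)
        h = ad.reshape(h, (b, self.config.encoder_channels[-1]) + (self.bottom,) * 3)
        for i, deconv in enumerate(self.dec):
            h = deconv(h)
            if i < len(self.dec) - 1:
                h = ad.leaky_relu(self.dec_bn[i](h, training=self.training), self.slope)
        return ad.sigmoid(h)


class Critic(nn.Module):
    """Stride-1 convolutions with one 2x max-pooling per layer (applied at
    the start of the layer, halving the grid the convolution runs on);
    latent-vector output through a dense head with sigmoid activation."""

    def __init__(self, config: CriticConfig, volume_size: int, rng):
        self.config = config
        self.volume_size = int(volume_size)
        k, ch = config.kernel, config.channels
        self.slope = config.leaky_slope
        cin = 2
        self.convs = []
        for c in ch:
            self.convs.append(nn.Conv3d(rng, cin, c, k, stride=1))
            cin = c
        self.bottom = self.volume_size // 16
        self.fc = nn.Dense(rng, ch[-1] * self.bottom**3, config.latent_dim)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 2:
            raise ValueError("critic expects two-channel combined input")
        h = x
        for i, conv in enumerate(self.convs):
            h = nn.max_pool3d(h)
            h = conv(h)
            if i < len(self.convs) - 1:
                h = ad.leaky_relu(h, self.slope)
        h = ad.reshape(h, (h.shape[0], -1))
        return ad.sigmoid(self.fc(h))


# ----------------------------------------------------------------------
# training / inference
# ----------------------------------------------------------------------

@dataclass
class GanHistory:
    generator_loss: list = field(default_factory=list)
    critic_loss: list = field(default_factory=list)
    cross_entropy: list = field(default_factory=list)


def train_gan(
    volumes,
    masks,
    gen_config: GeneratorConfig | None = None,
    critic_config: CriticConfig | None = None,
    weights: LossWeights | None = None,
    epochs: int = 30,
    batch_size: int = 8,
    lr: float = 1e-4,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    critic_steps: int = 1,
    seed: int = 0,
) -> tuple[Generator, Critic, GanHistory]:
    """Alternating WGAN-GP + cross-entropy training; deterministic given seed.

    ``volumes`` and ``masks`` are equal-length sequences of same-sized cubes
    (intensities in [0, 1], masks binary).
    """
    vols = [np.asarray(v, dtype=nn.DTYPE) for v in volumes]
    msks = [np.asarray(m, dtype=nn.DTYPE) for m in masks]
    if len(vols) == 0 or len(vols) != len(msks):
        raise ValueError("need equally many volumes and masks")
    size = vols[0].shape
    if any(v.shape != size or m.shape != size for v, m in zip(vols, msks)):
        raise ValueError("all volumes/masks must share one cube size")

    weights = weights or LossWeights()
    gen_config = gen_config or GeneratorConfig()
    critic_config = critic_config or CriticConfig()
    rng = np.random.default_rng(seed)
    gen = Generator(gen_config, size[0], rng)
    critic = Critic(critic_config, size[0], rng)
    g_opt = nn.Adam(gen.parameters(), lr=lr, beta1=beta1, beta2=beta2, eps=eps)
    c_opt = nn.Adam(critic.parameters(), lr=lr, beta1=beta1, beta2=beta2, eps=eps)

    x_all = np.stack(vols)[:, None]   # (N, 1, D, H, W)
    y_all = np.stack(msks)[:, None]
    n = len(vols)
    hist = GanHistory()

    for _epoch in range(epochs):
        order = rng.permutation(n)
        ep_g, ep_c, ep_ce = [], [], []
        for start in range(0, n - n % batch_size or n, batch_size):
            sel = order[start : start + batch_size]
            if len(sel) == 0:
                continue
            vb = Tensor(x_all[sel])
            yb = Tensor(y_all[sel])

            # critic update(s): generator output treated as constant
            with ad.no_grad():
                x_fake = gen(vb)
            for _ in range(critic_steps):
                alpha = rng.uniform(0.0, 1.0, size=(len(sel), 1, 1, 1, 1)).astype(nn.DTYPE)
                x_hat = alpha * y_all[sel] + (1.0 - alpha) * x_fake.data
                xp = combine(Tensor(x_fake.data), vb)
                yp = combine(yb, vb)
                xhp = combine(Tensor(x_hat), vb)
                c_loss = critic_loss(critic, xp, yp, xhp, weights)
                c_grads = ad.grad(c_loss, critic.parameters())
                c_opt.step(c_grads)

            # generator update
            x = gen(vb)
            xp = combine(x, vb)
            fake_out = critic(xp)
            g_loss = generator_loss(fake_out, x, yb, weights)
            g_grads = ad.grad(g_loss, gen.parameters())
            g_opt.step(g_grads)

            if not (np.isfinite(g_loss.item()) and np.isfinite(c_loss.item())):
                raise FloatingPointError("non-finite loss during GAN training")
            ep_g.append(float(g_loss.item()))
            ep_c.append(float(c_loss.item()))
            with ad.no_grad():
                ep_ce.append(float(cross_entropy(Tensor(x.data), yb).item()))
        hist.generator_loss.append(float(np.mean(ep_g)))
        hist.critic_loss.append(float(np.mean(ep_c)))
        hist.cross_entropy.append(float(np.mean(ep_ce)))
    return gen, critic, hist


def predict_mask(generator: Generator, volume) -> np.ndarray:
    """Soft plane mask in [0, 1] with the same dims as the cropped volume."""
    vol = np.asarray(volume, dtype=nn.DTYPE)
    if vol.shape != (generator.volume_size,) * 3:
        raise ValueError(
            f"volume shape {vol.shape} does not match trained size "
            f"{(generator.volume_size,) * 3}"
        )
    was_training = getattr(generator, "training", True)
    generator.training = False
    try:
        with ad.no_grad():
            out = generator(Tensor(vol[None, None]))
    finally:
        generator.training = was_training
    return out.data[0, 0].astype(np.float32)
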