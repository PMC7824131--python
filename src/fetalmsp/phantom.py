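"""Synthetic fetal-head phantoms with a known mid-sagittal plane.

Each phantom is an ellipsoidal bright "skull" shell around a mid-intensity
interior, a dark central blob standing in for the diencephalon (the seed
landmark), paired internal features placed mirror-symmetrically about the
ground-truth plane, distinctive on-plane features (a bright nasal-tip-like
blob and a dark nuchal band, both lying in the plane so they do not break
its mirror symmetry), and a nose-like protrusion whose side encodes the
left/right head orientation. The volume is blurred and degraded with
multiplicative speckle-like noise, the dominant noise structure of B-mode
ultrasound.

The geometry parameters (shell radius ~0.35 of the smallest dimension, blob
radius ~0.06) are test fixtures, not anatomical claims. The ground-truth
plane is oblique by angles within a configurable envelope (default ±30°),
mirroring the inclusion baseline of the clinical protocol the phantom
emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Plane, plane_from_angles, rasterize_plane


class InvalidSpecError(ValueError):
    """Raised when the phantom spec cannot contain a head."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation conditions for one phantom cohort.

    ``noise_level`` is the variance of the unit-mean multiplicative speckle
    factor (0 disables noise). ``head_side`` is 'left', 'right' or 'random'.
    """

    dims: tuple[int, int, int] = (80, 80, 80)
    angle_limit: float = 30.0
    noise_level: float = 0.1
    head_side: str = "random"
    rng_seed: int = 0

    def __post_init__(self):
        if self.head_side not in ("left", "right", "random"):
            raise InvalidSpecError(f"unknown head_side {self.head_side!r}")
        if self.noise_level < 0:
            raise InvalidSpecError("noise_level must be >= 0")


@dataclass
class PhantomSample:
    """One synthetic case: volume plus fully consistent ground truth."""

    volume: np.ndarray
    gt_plane: Plane
    gt_seed: np.ndarray
    gt_mask: np.ndarray
    theta_axi: float
    theta_cor: float
    head_side: str
    head_label: np.ndarray = field(repr=False, default=None)


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, w): u = plane normal, v ~ axis 1, w ~ axis 2 for near-sagittal planes."""
    u = normal / np.linalg.norm(normal)
    v = np.array([0.0, 1.0, 0.0]) - u[1] * u
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


def _ball(dist2: np.ndarray, radius: float) -> np.ndarray:
    return dist2 <= radius * radius


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; deterministic given ``spec.rng_seed``."""
    dims = tuple(int(n) for n in spec.dims)
    if min(dims) < 16:
        raise InvalidSpecError(f"dims {dims} too small to contain a head (min 16)")
    rng = np.random.default_rng(spec.rng_seed)

    m = float(min(dims))
    center = np.array(dims, dtype=float) / 2.0 - 0.5
    seed = center + rng.uniform(-0.02, 0.02, size=3) * m
    theta_axi = float(rng.uniform(-spec.angle_limit, spec.angle_limit))
    theta_cor = float(rng.uniform(-spec.angle_limit, spec.angle_limit))
    side = spec.head_side
    if side == "random":
        side = "right" if rng.random() < 0.5 else "left"

    plane = plane_from_angles(seed, theta_axi, theta_cor)
    u, v, w = _orthonormal_frame(plane.normal)

    # head-frame coordinates of every voxel center
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in dims], indexing="ij"), axis=-1
    )
    rel = grid - seed
    uu = rel @ u
    vv = rel @ v
    ww = rel @ w

    ru, rv, rw = 0.30 * m, 0.36 * m, 0.34 * m
    r = np.sqrt((uu / ru) ** 2 + (vv / rv) ** 2 + (ww / rw) ** 2)

    vol = np.full(dims, 0.05)
    vol[r < 1.0] = 0.35
    vol[np.abs(r - 1.0) < 0.07] = 0.85

    def blob(cu, cv, cw, radius, value):
        d2 = (uu - cu) ** 2 + (vv - cv) ** 2 + (ww - cw) ** 2
        vol[_ball(d2, radius)] = value

    # paired features, mirror-symmetric about the plane (symmetric in uu)
    rf = 0.055 * m
    for cu, cv, cw, val in (
        (0.45 * ru, 0.30 * rv, 0.15 * rw, 0.75),
        (-0.45 * ru, 0.30 * rv, 0.15 * rw, 0.75),
        (0.40 * ru, -0.35 * rv, -0.20 * rw, 0.65),
        (-0.40 * ru, -0.35 * rv, -0.20 * rw, 0.65),
    ):
        blob(cu, cv, cw, rf, val)

    # on-plane features: bright nasal-tip analogue, dark nuchal band
    blob(0.0, 0.55 * rv, 0.40 * rw, 0.05 * m, 0.9)
    blob(0.0, -0.60 * rv, 0.25 * rw, 0.06 * m, 0.12)

    # nose marker outside the shell, on the plane, side encodes orientation
    wsign = 1.0 if side == "right" else -1.0
    blob(0.0, 0.0, wsign * (rw + 0.10 * m), 0.05 * m + 1.0, 0.9)

    # dark central diencephalon blob at the seed point
    rb = 0.09 * m
    dien2 = uu**2 + vv**2 + ww**2
    vol[_ball(dien2, rb)] = 0.05
    head_label = _ball(dien2, rb).astype(np.float32)

    vol = ndimage.gaussian_filter(vol, sigma=1.0)
    if spec.noise_level > 0:
        k = 1.0 / spec.noise_level  # gamma shape: unit mean, variance = noise_level
        vol = vol * rng.gamma(k, 1.0 / k, size=dims)
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)

    gt_mask = rasterize_plane(plane, dims, 0.5)
    return PhantomSample(
        volume=vol,
        gt_plane=plane,
        gt_seed=seed,
        gt_mask=gt_mask,
        theta_axi=theta_axi,
        theta_cor=theta_cor,
        head_side=side,
        head_label=head_label,
    )


def generate_dataset(n: int, spec: PhantomSpec) -> list[PhantomSample]:
    """``n`` independent phantoms with per-sample seeds derived from the spec seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(spec.rng_seed).spawn(n)
    samples = []
    for child in children:
        sub = int(child.generate_state(1)[0] % (2**31))
        sample_spec = PhantomSpec(
            dims=spec.dims,
            angle_limit=spec.angle_limit,
            noise_level=spec.noise_level,
            head_side=spec.head_side,
            rng_seed=sub,
        )
        samples.append(generate_phantom(sample_spec))
    return samples
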