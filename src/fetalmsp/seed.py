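"""Stage 1: locating the fetal-head seed point with a 2D network cascade.

Four networks cooperate: two segmentation networks (U-net encoder-decoder
with an atrous-spatial-pyramid-pooling block at the bottleneck) that segment
the dark central diencephalon region on sagittal and axial slices, and two
single-box object-detection networks (anchor-free center+size regression
with an objectness score) on axial and coronal views.

View conventions (see :mod:`fetalmsp.geometry`): sagittal slices fix axis 0
(in-plane coordinates are axes 1, 2), axial slices fix axis 2 (in-plane
axes 0, 1), coronal slices fix axis 1 (in-plane axes 0, 2). The cascade
refines the estimate in five steps:

1. segmentation on the central sagittal slice -> in-plane location (y, z);
2. detection on the axial view at z -> left-right coordinate x;
3. detection on the coronal view at y -> second x estimate (averaged);
4. segmentation on the sagittal slice at the updated x -> refined (y, z);
5. the second segmentation network on the axial view at z -> refined x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


class DetectionFailureError(RuntimeError):
    """No head found; carries the cascade stage (1-5) that failed."""

    def __init__(self, stage: int, message: str = ""):
        self.stage = stage
        super().__init__(f"seed detection failed at stage {stage}: {message}")


@dataclass(frozen=True)
class SeedPoint:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def rounded(self) -> tuple[int, int, int]:
        """Round half-up to integer voxel indices (used for cropping)."""
        return tuple(int(np.floor(v + 0.5)) for v in (self.x, self.y, self.z))


@dataclass(frozen=True)
class SeedCascadeConfig:
    """Architecture and training hyperparameters for the stage-1 cascade."""

    seg_base_channels: int = 8
    seg_depth: int = 2
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    det_channels: tuple[int, int, int] = (8, 16, 32)
    seg_batch: int = 10
    det_batch: int = 5
    seg_steps: int = 500
    det_steps: int = 400
    seg_lr: float = 1e-3
    det_lr: float = 0.01
    det_momentum: float = 0.9
    det_weight_decay: float = 5e-4
    seg_threshold: float = 0.5
    obj_threshold: float = 0.5


class UNetASPP(nn.Module):
    """2D U-net (depth 2) with an ASPP bottleneck; per-pixel sigmoid output.

    The ASPP block probes the bottleneck features with parallel dilated
    convolutions at the configured rates and fuses them with a 1x1
    convolution, enlarging the receptive field at fixed resolution.
    """

    def __init__(self, config: SeedCascadeConfig, rng):
        c = config.seg_base_channels
        self.depth = config.seg_depth
        self.enc1a = nn.Conv2d(rng, 1, c, 3)
        self.enc1b = nn.Conv2d(rng, c, c, 3)
        self.enc2a = nn.Conv2d(rng, c, 2 * c, 3)
        self.enc2b = nn.Conv2d(rng, 2 * c, 2 * c, 3)
        self.aspp = [
            nn.Conv2d(rng, 2 * c, 2 * c, 3, dilation=r) for r in config.aspp_rates
        ]
        self.fuse = nn.Conv2d(rng, 2 * c * len(config.aspp_rates), 4 * c, 1)
        self.up1 = nn.ConvTranspose2d(rng, 4 * c, 2 * c, 2, stride=2)
        self.dec1 = nn.Conv2d(rng, 4 * c, 2 * c, 3)
        self.up2 = nn.ConvTranspose2d(rng, 2 * c, c, 2, stride=2)
        self.dec2 = nn.Conv2d(rng, 2 * c, c, 3)
        self.head = nn.Conv2d(rng, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        if any(s % 2**self.depth for s in x.shape[2:]):
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by 2^{self.depth}"
            )
        s1 = ad.leaky_relu(self.enc1b(ad.leaky_relu(self.enc1a(x))))
        h = nn.max_pool2d(s1)
        s2 = ad.leaky_relu(self.enc2b(ad.leaky_relu(self.enc2a(h))))
        h = nn.max_pool2d(s2)
        pyr = [ad.leaky_relu(conv(h)) for conv in self.aspp]
        h = ad.leaky_relu(self.fuse(ad.concat(pyr, axis=1)))
        h = self.up1(h)
        h = ad.leaky_relu(self.dec1(ad.concat([h, s2], axis=1)))
        h = self.up2(h)
        h = ad.leaky_relu(self.dec2(ad.concat([h, s1], axis=1)))
        return ad.sigmoid(self.head(h))


class DetectNet(nn.Module):
    """Single-box detector: objectness plus normalized center/extent.

    Output per slice is (objectness, cx, cy, w, h), all through sigmoids so
    box coordinates are intrinsically clamped to the slice.
    """

    def __init__(self, config: SeedCascadeConfig, slice_size: int, rng):
        chans = config.det_channels
        self.slice_size = int(slice_size)
        cin = 1
        self.convs = []
        for c in chans:
            self.convs.append(nn.Conv2d(rng, cin, c, 3, stride=2))
            cin = c
        final = slice_size // 2 ** len(chans)
        self.fc1 = nn.Dense(rng, chans[-1] * final * final, 64)
        self.fc2 = nn.Dense(rng, 64, 5)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv(h))
        h = ad.reshape(h, (h.shape[0], -1))
        h = ad.leaky_relu(self.fc1(h))
        return ad.sigmoid(self.fc2(h))


def build_segmentation_net(config: SeedCascadeConfig, rng=None) -> UNetASPP:
    return UNetASPP(config, rng if rng is not None else np.random.default_rng(0))


def build_detection_net(config: SeedCascadeConfig, slice_size: int, rng=None) -> DetectNet:
    return DetectNet(config, slice_size, rng if rng is not None else np.random.default_rng(0))


@dataclass
class SeedModels:
    seg_sagittal: UNetASPP
    seg_axial: UNetASPP
    det_axial: DetectNet
    det_coronal: DetectNet
    config: SeedCascadeConfig = field(default_factory=SeedCascadeConfig)


# ----------------------------------------------------------------------
# view slicing
# ----------------------------------------------------------------------

def view_slice(volume: np.ndarray, view: str, index: int) -> np.ndarray:
    """Extract a 2D slice; index is clipped into the volume."""
    if view == "sagittal":
        i = int(np.clip(index, 0, volume.shape[0] - 1))
        return volume[i, :, :]
    if view == "axial":
        k = int(np.clip(index, 0, volume.shape[2] - 1))
        return volume[:, :, k]
    if view == "coronal":
        j = int(np.clip(index, 0, volume.shape[1] - 1))
        return volume[:, j, :]
    raise ValueError(f"unknown view {view!r}")


_VIEW_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}
# in-plane volume axes of each view, in (row, col) order of the slice
_VIEW_INPLANE = {"sagittal": (1, 2), "axial": (0, 1), "coronal": (0, 2)}


# ----------------------------------------------------------------------
# training data extraction from phantoms
# ----------------------------------------------------------------------

def _seg_examples(sample, view: str, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    """(slice, label) pairs: slices through the blob plus off-blob negatives."""
    ax = _VIEW_AXIS[view]
    n = sample.volume.shape[ax]
    center = int(round(sample.gt_seed[ax]))
    out = []
    for off in (-1, 0, 1):
        i = int(np.clip(center + off, 0, n - 1))
        out.append((view_slice(sample.volume, view, i),
                    view_slice(sample.head_label, view, i)))
    for _ in range(2):
        i = int(rng.integers(0, n))
        while abs(i - center) <= 3:
            i = int(rng.integers(0, n))
        out.append((view_slice(sample.volume, view, i),
                    view_slice(sample.head_label, view, i)))
    return out


def _det_examples(sample, view: str, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    """(slice, target) pairs; target = (obj, cx, cy, w, h) normalized."""
    ax = _VIEW_AXIS[view]
    r0, r1 = _VIEW_INPLANE[view]
    n = sample.volume.shape[ax]
    dims = sample.volume.shape
    center = int(round(sample.gt_seed[ax]))
    blob_r = 0.09 * min(dims) + 1.0
    cx = sample.gt_seed[r0] / dims[r0]
    cy = sample.gt_seed[r1] / dims[r1]
    w = 2 * blob_r / dims[r0]
    h = 2 * blob_r / dims[r1]
    out = []
    for off in (-1, 0, 1):
        i = int(np.clip(center + off, 0, n - 1))
        out.append((view_slice(sample.volume, view, i),
                    np.array([1.0, cx, cy, w, h], dtype=np.float32)))
    for _ in range(2):
        i = int(rng.integers(0, n))
        while abs(i - center) <= int(blob_r) + 1:
            i = int(rng.integers(0, n))
        out.append((view_slice(sample.volume, view, i),
                    np.array([0.0, cx, cy, w, h], dtype=np.float32)))
    return out


def _train_segmentation(net: UNetASPP, examples, config, rng) -> list[float]:
    xs = np.stack([e[0] for e in examples])[:, None].astype(nn.DTYPE)
    ys = np.stack([e[1] for e in examples])[:, None].astype(nn.DTYPE)
    opt = nn.Adam(net.parameters(), lr=config.seg_lr)
    losses = []
    for _ in range(config.seg_steps):
        sel = rng.integers(0, len(xs), size=config.seg_batch)
        pred = net(Tensor(xs[sel]))
        loss = nn.binary_cross_entropy(pred, Tensor(ys[sel]))
        grads = ad.grad(loss, net.parameters())
        opt.step(grads)
        losses.append(float(loss.item()))
    return losses


def _train_detection(net: DetectNet, examples, config, rng) -> list[float]:
    xs = np.stack([e[0] for e in examples])[:, None].astype(nn.DTYPE)
    ts = np.stack([e[1] for e in examples]).astype(nn.DTYPE)
    opt = nn.SGD(net.parameters(), lr=config.det_lr,
                 momentum=config.det_momentum, weight_decay=config.det_weight_decay)
    losses = []
    for _ in range(config.det_steps):
        sel = rng.integers(0, len(xs), size=config.det_batch)
        pred = net(Tensor(xs[sel]))
        obj_t = Tensor(ts[sel][:, :1])
        box_t = Tensor(ts[sel][:, 1:])
        obj_loss = nn.binary_cross_entropy(pred[:, :1], obj_t)
        # box regression counts only on slices that contain the head
        mask = ts[sel][:, :1]
        box_loss = nn.huber(ad.mul(pred[:, 1:], Tensor(mask)),
                            ad.mul(box_t, Tensor(mask)))
        loss = ad.add(obj_loss, box_loss)
        grads = ad.grad(loss, net.parameters())
        opt.step(grads)
        losses.append(float(loss.item()))
    return losses


@dataclass
class SeedTrainingHistory:
    seg_sagittal: list = field(default_factory=list)
    seg_axial: list = field(default_factory=list)
    det_axial: list = field(default_factory=list)
    det_coronal: list = field(default_factory=list)


def train_seed_networks(
    dataset, config: SeedCascadeConfig | None = None, seed: int = 0
) -> tuple[SeedModels, SeedTrainingHistory]:
    """Train the four cascade networks on phantom samples; deterministic.

    Segmentation nets use Adam with binary cross-entropy (batch 10);
    detection nets use SGD with momentum 0.9 and weight decay 5e-4 on a
    cross-entropy (objectness) plus Huber (box) objective (batch 5).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    config = config or SeedCascadeConfig()
    rng = np.random.default_rng(seed)
    size = dataset[0].volume.shape[0]
    models = SeedModels(
        seg_sagittal=UNetASPP(config, rng),
        seg_axial=UNetASPP(config, rng),
        det_axial=DetectNet(config, size, rng),
        det_coronal=DetectNet(config, size, rng),
        config=config,
    )
    hist = SeedTrainingHistory()
    seg_sag, seg_ax, det_ax, det_cor = [], [], [], []
    for s in dataset:
        seg_sag += _seg_examples(s, "sagittal", rng)
        seg_ax += _seg_examples(s, "axial", rng)
        det_ax += _det_examples(s, "axial", rng)
        det_cor += _det_examples(s, "coronal", rng)
    hist.seg_sagittal = _train_segmentation(models.seg_sagittal, seg_sag, config, rng)
    hist.seg_axial = _train_segmentation(models.seg_axial, seg_ax, config, rng)
    hist.det_axial = _train_detection(models.det_axial, det_ax, config, rng)
    hist.det_coronal = _train_detection(models.det_coronal, det_cor, config, rng)
    return models, hist


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------

def _segment_centroid(net: UNetASPP, slc: np.ndarray, threshold: float):
    with ad.no_grad():
        prob = net(Tensor(slc[None, None].astype(nn.DTYPE))).data[0, 0]
    sel = prob > threshold
    if not sel.any():
        return None
    w = prob * sel
    idx = np.argwhere(sel)
    weights = w[sel]
    c = (idx * weights[:, None]).sum(axis=0) / weights.sum()
    return float(c[0]), float(c[1])


def _detect_box(net: DetectNet, slc: np.ndarray, threshold: float):
    with ad.no_grad():
        out = net(Tensor(slc[None, None].astype(nn.DTYPE))).data[0]
    if out[0] < threshold:
        return None
    return float(out[1]), float(out[2])


def detect_seed(volume: np.ndarray, models: SeedModels) -> SeedPoint:
    """Run the five-step cascade; raises :class:`DetectionFailureError`."""
    vol = np.asarray(volume, dtype=np.float32)
    cfg = models.config
    nx, ny, nz = vol.shape

    # 1: segmentation on the central sagittal slice -> (y, z)
    c = _segment_centroid(models.seg_sagittal, view_slice(vol, "sagittal", nx // 2),
                          cfg.seg_threshold)
    if c is None:
        raise DetectionFailureError(1, "empty segmentation on central sagittal slice")
    y, z = c

    # 2: detection on the axial view -> x
    box = _detect_box(models.det_axial, view_slice(vol, "axial", int(round(z))),
                      cfg.obj_threshold)
    if box is None:
        raise DetectionFailureError(2, "no box above threshold on axial view")
    x_ax = box[0] * nx

    # 3: detection on the coronal view -> second x estimate
    box = _detect_box(models.det_coronal, view_slice(vol, "coronal", int(round(y))),
                      cfg.obj_threshold)
    if box is None:
        raise DetectionFailureError(3, "no box above threshold on coronal view")
    x = 0.5 * (x_ax + box[0] * nx)

    # 4: segmentation again at the updated sagittal slice -> refined (y, z)
    c = _segment_centroid(models.seg_sagittal,
                          view_slice(vol, "sagittal", int(round(x))),
                          cfg.seg_threshold)
    if c is None:
        raise DetectionFailureError(4, "empty segmentation on refined sagittal slice")
    y, z = c

    # 5: second segmentation network on the axial view -> refined x
    c = _segment_centroid(models.seg_axial, view_slice(vol, "axial", int(round(z))),
                          cfg.seg_threshold)
    if c is None:
        raise DetectionFailureError(5, "empty segmentation on axial view")
    x = c[0]

    return SeedPoint(float(x), float(y), float(z))
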