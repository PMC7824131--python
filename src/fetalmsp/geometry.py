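"""Plane parameterization, rasterization, rigid transforms and slice extraction.

The central object is a plane ``ax + by + cz + d = 0`` in 0-based voxel
coordinates, stored as a unit-norm coefficient 4-vector with a fixed sign
convention (first nonzero component of the normal is positive), so that the
coefficient-space evaluation metrics are well defined.

Axis convention: axis 0 is left–right, i.e. the mid-sagittal plane of a
well-aligned head has a normal dominated by axis 0. Sagittal slices are
``volume[i, :, :]``; axial slices fix axis 2 and coronal slices fix axis 1.
The obliquity angle seen on axial slices (``theta_axi``) is a rotation of
the sagittal plane about the volume z-axis, and the one seen on coronal
slices (``theta_cor``) a subsequent rotation about the y-axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class InvalidPlaneError(ValueError):
    """Raised when a coefficient vector has no normal direction."""


class InsufficientSupportError(ValueError):
    """Raised when a mask has fewer than 3 voxels above threshold."""


class DegenerateFitError(ValueError):
    """Raised when the supporting voxels are (near-)collinear."""


class EmptySliceError(ValueError):
    """Raised when a plane does not intersect the volume box."""


class PlaneOutsideVolumeWarning(UserWarning):
    """Signals an all-zero rasterization (plane misses the volume)."""


_EPS = 1e-12


@dataclass(frozen=True)
class Plane:
    """A normalized plane ``ax + by + cz + d = 0`` in voxel coordinates."""

    a: float
    b: float
    c: float
    d: float

    @property
    def vector(self) -> np.ndarray:
        """Coefficient 4-vector (unit norm)."""
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    @property
    def normal(self) -> np.ndarray:
        """Unit 3-vector normal."""
        n = np.array([self.a, self.b, self.c], dtype=float)
        return n / np.linalg.norm(n)

    @property
    def offset(self) -> float:
        """Signed distance of the origin to the plane (geometric d)."""
        n = np.linalg.norm([self.a, self.b, self.c])
        return self.d / n

    def signed_distance(self, points) -> np.ndarray:
        """Perpendicular signed distance of ``points`` (..., 3) in voxels."""
        pts = np.asarray(points, dtype=float)
        return (pts @ self.normal) + self.offset

    def recentered(self, origin) -> "Plane":
        """The same plane expressed with ``origin`` as coordinate origin."""
        origin = np.asarray(origin, dtype=float)
        n = self.normal
        return normalize_plane([n[0], n[1], n[2], self.signed_distance(origin)])


def normalize_plane(coeffs) -> Plane:
    """Normalize raw coefficients to a unit 4-vector with canonical sign.

    Raises :class:`InvalidPlaneError` if the normal part is (numerically)
    zero or any entry is not finite. Idempotent.
    """
    v = np.asarray(coeffs, dtype=float).reshape(4)
    if not np.all(np.isfinite(v)):
        raise InvalidPlaneError("plane coefficients must be finite")
    if np.linalg.norm(v[:3]) <= _EPS * max(1.0, np.linalg.norm(v)):
        raise InvalidPlaneError("degenerate plane: normal (a,b,c) is zero")
    v = v / np.linalg.norm(v)
    for comp in v[:3]:
        if abs(comp) > _EPS:
            if comp < 0:
                v = -v
            break
    return Plane(*v)


def _rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def plane_from_angles(seed, theta_axi: float, theta_cor: float) -> Plane:
    """Oblique sagittal plane through ``seed``.

    Starts from the sagittal plane through the seed point (normal along the
    left–right axis 0), tilts it by ``theta_axi`` (the rotation visible on
    axial slices) and then by ``theta_cor`` (visible on coronal slices).
    Angles in degrees.
    """
    seed = np.asarray(seed, dtype=float).reshape(3)
    if not (np.all(np.isfinite(seed)) and np.isfinite(theta_axi) and np.isfinite(theta_cor)):
        raise ValueError("seed and angles must be finite")
    n = _rot_y(theta_cor) @ _rot_z(theta_axi) @ np.array([1.0, 0.0, 0.0])
    d = -float(n @ seed)
    return normalize_plane([n[0], n[1], n[2], d])


def angles_from_plane(plane: Plane) -> tuple[float, float]:
    """Invert :func:`plane_from_angles` (valid for obliquity < 90 deg)."""
    n = plane.normal
    if n[0] < 0:
        n = -n
    theta_axi = np.rad2deg(np.arcsin(np.clip(n[1], -1.0, 1.0)))
    theta_cor = np.rad2deg(np.arctan2(-n[2], n[0]))
    return float(theta_axi), float(theta_cor)


def dihedral_angle(p1: Plane, p2: Plane) -> float:
    """Angle between the two planes' normals, in degrees, in [0, 90]."""
    c = abs(float(p1.normal @ p2.normal))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def rasterize_plane(plane: Plane, dims, half_thickness: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where a voxel center is within ``half_thickness`` of the plane.

    Emits :class:`PlaneOutsideVolumeWarning` and returns all zeros when the
    plane misses the volume box.
    """
    if half_thickness <= 0:
        raise ValueError("half_thickness must be positive")
    dims = tuple(int(n) for n in dims)
    if any(n < 1 for n in dims):
        raise ValueError("dims must be >= 1")
    n = plane.normal
    d0 = plane.offset
    x, y, z = np.ogrid[: dims[0], : dims[1], : dims[2]]
    dist = np.abs(n[0] * x + n[1] * y + n[2] * z + d0)
    mask = (dist <= half_thickness).astype(np.float32)
    if not mask.any():
        warnings.warn(
            "plane does not intersect the volume; mask is all zero",
            PlaneOutsideVolumeWarning,
            stacklevel=2,
        )
    return mask


def fit_plane_from_mask(mask, threshold: float = 0.5) -> Plane:
    """Weighted total-least-squares plane through above-threshold voxel centers.

    Voxels with value above ``threshold`` contribute with weight equal to
    their mask value; the plane normal is the smallest principal axis of the
    weighted, centered scatter (smallest singular vector).
    """
    mask = np.asarray(mask, dtype=float)
    sel = mask > threshold
    pts = np.argwhere(sel).astype(float)
    if pts.shape[0] < 3:
        raise InsufficientSupportError(
            f"only {pts.shape[0]} voxels above threshold {threshold}"
        )
    w = mask[sel]
    wsum = w.sum()
    centroid = (pts * w[:, None]).sum(axis=0) / wsum
    x = (pts - centroid) * np.sqrt(w)[:, None]
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateFitError("supporting voxels are collinear")
    n = vt[2]
    d = -float(n @ centroid)
    return normalize_plane([n[0], n[1], n[2], d])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p -> R p + t`` between two planes (M = TR)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("R must be a proper rotation")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.t
        return m


def _minimal_rotation(n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector n1 onto unit vector n2."""
    axis = np.cross(n1, n2)
    s2 = float(axis @ axis)
    c = float(n1 @ n2)
    if s2 < 1e-24:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate by pi about any axis orthogonal to n1
        u = np.cross(n1, [1.0, 0.0, 0.0])
        if u @ u < 1e-12:
            u = np.cross(n1, [0.0, 1.0, 0.0])
        u = u / np.linalg.norm(u)
        return 2.0 * np.outer(u, u) - np.eye(3)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / s2)


def transform_between_planes(initial: Plane, target: Plane) -> RigidTransform:
    """Rigid transform M = TR mapping points of ``initial`` onto ``target``.

    R is the minimal rotation aligning the normals; T translates the rotated
    plane onto the target along the target normal.
    """
    n1, n2 = initial.normal, target.normal
    R = _minimal_rotation(n1, n2)
    p0 = -initial.offset * n1  # closest point of the initial plane to origin
    t = (-target.offset - float(n2 @ (R @ p0))) * n2
    return RigidTransform(R, t)


def _plane_intersects_box(plane: Plane, dims, margin: float = 0.0) -> bool:
    corners = np.array(
        [[x, y, z] for x in (0, dims[0] - 1) for y in (0, dims[1] - 1) for z in (0, dims[2] - 1)],
        dtype=float,
    )
    d = plane.signed_distance(corners)
    return bool(d.min() <= margin and d.max() >= -margin)


def extract_msp_image(volume, plane: Plane, out_dims=None, order: int = 1) -> np.ndarray:
    """Resample the volume on a regular 2D grid of the plane.

    Pixel (p, q) of the initial axis-aligned sagittal plane (the plane
    ``x = 0``, i.e. 3D point (0, p, q)) is carried onto the target plane by
    the rigid transform M = TR, and the volume is interpolated there
    (``order=1`` trilinear, ``order=0`` nearest neighbor). Samples falling
    outside the volume are 0. For an axis-aligned plane ``x = k`` the result
    equals the stored slice ``volume[k]`` exactly.
    """
    vol = np.asarray(volume, dtype=float)
    plane = normalize_plane(plane.vector)  # invariance to rescaling by contract
    if not _plane_intersects_box(plane, vol.shape, margin=0.5):
        raise EmptySliceError("plane does not intersect the volume")
    if out_dims is None:
        out_dims = (vol.shape[1], vol.shape[2])
    initial = Plane(1.0, 0.0, 0.0, 0.0)
    m = transform_between_planes(initial, plane)
    p, q = np.meshgrid(np.arange(out_dims[0]), np.arange(out_dims[1]), indexing="ij")
    pts = np.stack([np.zeros_like(p, dtype=float), p.astype(float), q.astype(float)], axis=-1)
    mapped = m.apply(pts.reshape(-1, 3)).reshape(pts.shape)
    coords = np.moveaxis(mapped, -1, 0)
    return ndimage.map_coordinates(vol, coords, order=order, mode="constant", cval=0.0)


def reflect_points(points, plane: Plane) -> np.ndarray:
    """Mirror image of ``points`` (..., 3) across the plane."""
    pts = np.asarray(points, dtype=float)
    d = plane.signed_distance(pts)
    return pts - 2.0 * d[..., None] * plane.normal


def reflect_volume(volume, plane: Plane, order: int = 1) -> np.ndarray:
    """Resample the volume at voxel positions mirrored across the plane."""
    vol = np.asarray(volume, dtype=float)
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in vol.shape], indexing="ij"),
        axis=-1,
    )
    refl = reflect_points(grid.reshape(-1, 3), plane).reshape(grid.shape)
    coords = np.moveaxis(refl, -1, 0)
    return ndimage.map_coordinates(vol, coords, order=order, mode="constant", cval=0.0)
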