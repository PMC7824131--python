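"""Readers and writers for volumes, plane records and 2D slice images.

Volumes: NIfTI (.nii/.nii.gz) through nibabel, MetaImage (.mha/.mhd)
through SimpleITK. Geometry is voxel-based throughout the package; physical
spacing is carried as metadata only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Plane, normalize_plane


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a volume; returns (array, voxel spacing)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); keep our axis-0-first layout
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float32)
        return data, tuple(float(s) for s in img.GetSpacing())
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(path, volume: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
        return
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(volume, (2, 1, 0)), dtype=np.float32)
        )
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def plane_record(plane: Plane, seed=None, theta_axi=None, theta_cor=None) -> dict:
    rec = {"a": plane.a, "b": plane.b, "c": plane.c, "d": plane.d}
    if seed is not None:
        rec["seed"] = [float(v) for v in np.asarray(seed).reshape(3)]
    if theta_axi is not None:
        rec["theta_axi"] = float(theta_axi)
    if theta_cor is not None:
        rec["theta_cor"] = float(theta_cor)
    return rec


def write_plane_json(path, plane: Plane, **kwargs) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(plane_record(plane, **kwargs), indent=2))


def read_plane_json(path) -> tuple[Plane, dict]:
    rec = json.loads(Path(path).read_text())
    plane = normalize_plane([rec["a"], rec["b"], rec["c"], rec["d"]])
    return plane, rec


def write_png(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG; the image is rescaled from its [0, 1] range."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), (arr * 255).astype(np.uint8))
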