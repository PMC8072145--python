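"""Thin readers/writers for the on-disk cohort formats."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

__all__ = [
    "read_image",
    "write_png",
    "read_volume",
    "write_nifti",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_png(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="PNG")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume; returns (array, spacing_mm)."""
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk  # optional format, imported on demand

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        return np.asarray(arr), tuple(float(s) for s in spacing)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return arr, spacing


def write_nifti(
    path: str | Path, array: np.ndarray, spacing: tuple[float, float, float]
) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
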