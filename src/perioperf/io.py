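"""NIfTI-1 I/O helpers (spacing carried in the header/affine)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti"]


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write a 3-D or 4-D volume with voxel spacing (mm) on the diagonal
    affine.  Integer arrays are preserved as such."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(spacing) + [1.0])
    arr = np.asarray(data)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, affine)
    if arr.ndim == 4:
        img.header.set_zooms(tuple(spacing) + (1.0,))
    img.to_filename(str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns the array and its voxel spacing in mm."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)
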