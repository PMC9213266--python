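"""Thin NIfTI-1 read/write helpers (RAS+ diagonal affines)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume"]


def save_volume(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a 3-D volume as NIfTI-1 with a diagonal RAS+ affine."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.float64)
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def load_volume(path) -> np.ndarray:
    """Load a NIfTI volume as a float64 array (voxel order as stored)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)
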