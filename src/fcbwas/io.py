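"""Shared readers/writers: NIfTI volumes, link vectors (HDF5), coordinate maps."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np


def read_nifti(path):
    """Load a NIfTI-1 file -> (array, affine, header).

    The sform affine wins when qform and sform disagree (nibabel's
    ``get_best_affine`` convention).
    """
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine, img.header


def write_nifti(path, array: np.ndarray, affine: np.ndarray, dtype=None) -> Path:
    arr = np.asarray(array)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))
    return Path(path)


def voxel_to_mm(voxel_index, affine: np.ndarray) -> np.ndarray:
    """Map voxel indices to mm coordinates via the affine (homogeneous mult)."""
    idx = np.atleast_2d(np.asarray(voxel_index, dtype=float))
    hom = np.column_stack([idx, np.ones(len(idx))])
    mm = (np.asarray(affine, dtype=float) @ hom.T).T[:, :3]
    return mm[0] if np.ndim(voxel_index) == 1 else mm


def save_link_vectors(path, **vectors) -> Path:
    """Store named upper-triangle link vectors in one HDF5 file.

    The canonical layout is 0-based, row-major over the strict upper
    triangle (see ``connectivity.link_index``).
    """
    with h5py.File(path, "w") as f:
        f.attrs["link_order"] = "upper-triangle, 0-based, row-major"
        for name, vec in vectors.items():
            f.create_dataset(name, data=np.asarray(vec))
    return Path(path)


def load_link_vectors(path, names=None) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name in names if names is not None else f.keys():
            out[name] = f[name][()]
    return out
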