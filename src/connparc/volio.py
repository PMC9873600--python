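"""NIfTI volume I/O and grid bookkeeping.

All volumes in this package are plain numpy arrays paired with a 4x4 RAS
affine (voxel index -> world mm). Voxel indices are 0-based; seed voxels are
enumerated in a deterministic x-fastest scan order (see
:func:`seed_scan_order`).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "seed_scan_order",
    "voxel_volume_mm3",
    "world_coordinates",
]


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid/affine do not."""


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume, returning ``(data, affine)``.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    nibabel.filebasedimages.ImageFileError
        If the file is not a readable NIfTI image.
    """
    img = nib.load(os.fspath(path))
    return np.asanyarray(img.dataobj), np.asarray(img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    """Write *data* with *affine* as NIfTI-1. Round-trips exactly for
    integer and float arrays."""
    data = np.asarray(data)
    # NIfTI-1 has no int64/bool on-disk type that nibabel writes silently.
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    nib.save(img, os.fspath(path))


def check_same_grid(
    shapes_affines: list[tuple[tuple[int, ...], np.ndarray]],
    names: list[str] | None = None,
    atol: float = 1e-6,
) -> None:
    """Verify all ``(shape, affine)`` pairs agree; raise naming the offender."""
    if not shapes_affines:
        return
    ref_shape, ref_aff = shapes_affines[0]
    ref_aff = np.asarray(ref_aff)
    for i, (shape, aff) in enumerate(shapes_affines[1:], start=1):
        name = names[i] if names else f"volume #{i}"
        if tuple(shape) != tuple(ref_shape):
            raise GridMismatchError(
                f"{name}: shape {tuple(shape)} != reference {tuple(ref_shape)}"
            )
        if not np.allclose(aff, ref_aff, atol=atol):
            raise GridMismatchError(f"{name}: affine differs from reference")


def seed_scan_order(mask: np.ndarray) -> np.ndarray:
    """Return the (V, 3) integer voxel coordinates of ``mask``'s True voxels
    in deterministic x-fastest order (x varies fastest, then y, then z)."""
    mask = np.asarray(mask, dtype=bool)
    zz, yy, xx = np.nonzero(mask.transpose(2, 1, 0))
    return np.column_stack([xx, yy, zz]).astype(np.intp)


def world_coordinates(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map (V, 3) voxel indices to (V, 3) world mm via the affine."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    return voxels @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Volume of one voxel in mm^3: |det| of the affine's 3x3 block."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
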