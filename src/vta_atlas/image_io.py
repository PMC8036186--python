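"""NIfTI volume I/O and voxel/world geometry primitives.

All volumes in the toolkit are 3-D scalar grids paired with a 4x4 affine
mapping 0-based voxel indices to world millimetres (NIfTI convention: the
affine addresses voxel *centers*). Binary segmentation masks are stored as
unsigned 8-bit, probabilistic atlases as 32-bit float.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumetricImage",
    "BinaryMask",
    "GeometryError",
    "DimensionError",
    "MaskValidationError",
    "read_volume",
    "read_mask",
    "write_volume",
    "voxel_volume",
    "world_coords",
]


class GeometryError(ValueError):
    """Invalid or incompatible affine/grid geometry."""


class DimensionError(ValueError):
    """Input volume is not a 3-D scalar grid."""


class MaskValidationError(ValueError):
    """Data requested as a binary mask contains non-binary values."""


@dataclass
class VolumetricImage:
    """A 3-D scalar grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    affine : ndarray, shape (4, 4)
        Homogeneous map from 0-based voxel indices (voxel centers) to
        world coordinates in mm. The upper-left 3x3 block must be
        invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(
                f"expected a 3-D volume, got {self.data.ndim}-D data "
                f"(offending axes beyond the third: {self.data.shape[3:]})"
            )
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine upper-left 3x3 block is singular")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def same_grid(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        """True when the grids and affines coincide (shared space)."""
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "VolumetricImage") -> None:
        if not self.same_grid(other):
            raise GeometryError(
                f"volumes are not on a shared grid: shapes {self.grid_shape} vs "
                f"{other.grid_shape} or affines differ"
            )


class BinaryMask(VolumetricImage):
    """A VolumetricImage whose values are exactly 0 or 1 (stored uint8).

    All-zero masks are legal inputs (they arise from disjoint-rater
    conjunctions) but can be detected via :attr:`is_empty`.
    """

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        values = np.unique(data)
        if not np.isin(values, (0, 1)).all():
            shown = values[:10]
            raise MaskValidationError(
                f"mask contains non-binary values: {shown.tolist()}"
                + ("..." if values.size > 10 else "")
            )
        self.data = data.astype(np.uint8)
        super().__post_init__()

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_volume(path: str | os.PathLike) -> VolumetricImage:
    """Load a NIfTI-1 volume (.nii or .nii.gz).

    Header scl_slope/scl_inter scaling is honored (``get_fdata``); no
    other intensity rescaling is applied. Raises :class:`DimensionError`
    for 4-D inputs and ``FileNotFoundError``/``nibabel`` errors for
    unreadable files.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionError(
            f"{path}: expected 3-D volume, got shape {data.shape} "
            f"(offending axis 3 has length {data.shape[3] if data.ndim > 3 else '?'})"
        )
    return VolumetricImage(data=data, affine=np.asarray(img.affine))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Load a NIfTI volume and validate it as a binary mask.

    Masks whose values are not exactly {0, 1} after header scaling are
    rejected rather than re-thresholded.
    """
    vol = read_volume(path)
    return BinaryMask(data=vol.data, affine=vol.affine)


def write_volume(img: VolumetricImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; masks as uint8, other data as float32."""
    if isinstance(img, BinaryMask):
        data = img.data.astype(np.uint8)
    elif np.issubdtype(img.data.dtype, np.integer):
        data = img.data
    else:
        data = img.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, img.affine), os.fspath(path))


def voxel_volume(img: VolumetricImage) -> float:
    """Volume of one voxel in mm³: |det| of the affine's 3x3 block.

    Invariant under rotation of the grid; 0.7 mm isotropic -> 0.343 mm³.
    """
    det = np.linalg.det(img.affine[:3, :3])
    if abs(det) < 1e-12:
        raise GeometryError("singular affine: voxel volume undefined")
    return float(abs(det))


def voxel_spacing(img: VolumetricImage) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the affine)."""
    return np.linalg.norm(img.affine[:3, :3], axis=0)


def world_coords(img: VolumetricImage, indices: np.ndarray) -> np.ndarray:
    """Map voxel indices (n, 3) to world-mm coordinates of voxel centers.

    Raises ``IndexError`` for indices outside the grid.
    """
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    if idx.shape[1] != 3:
        raise ValueError(f"indices must be (n, 3), got {idx.shape}")
    shape = np.asarray(img.grid_shape)
    if (idx < 0).any() or (idx > shape - 1).any():
        bad = idx[((idx < 0) | (idx > shape - 1)).any(axis=1)][0]
        raise IndexError(f"voxel index {bad.tolist()} outside grid {img.grid_shape}")
    return idx @ img.affine[:3, :3].T + img.affine[:3, 3]
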