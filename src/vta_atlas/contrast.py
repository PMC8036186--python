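"""Multimodal midbrain-contrast fusion for delineation.

Reproduces the three preprocessing steps that produce the delineation
image: (1) average the 3rd and 4th echo of the T2*-weighted scan to
raise SNR, (2) z-score both the averaged echo and the T1-weighted image
over a pre-defined midbrain box, (3) sum the two normalized sections.
The fused image exists only over the box; the background is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GeometryError, VolumetricImage

__all__ = [
    "RoiBox",
    "DegenerateRoiError",
    "average_echoes",
    "normalize_roi",
    "fuse_contrast",
    "midbrain_contrast",
]


class DegenerateRoiError(ValueError):
    """ROI has zero intensity variance; normalization undefined."""


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box in voxel coordinates: inclusive corner + size."""

    corner: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"box size must be strictly positive, got {self.size}")
        if any(c < 0 for c in self.corner):
            raise ValueError(f"box corner must be non-negative, got {self.corner}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(c, c + s) for c, s in zip(self.corner, self.size)
        )  # type: ignore[return-value]

    def validate_in(self, img: VolumetricImage) -> None:
        for axis, (c, s, n) in enumerate(zip(self.corner, self.size, img.grid_shape)):
            if c + s > n:
                raise GeometryError(
                    f"ROI box exceeds grid on axis {axis}: corner {c} + size {s} > {n}"
                )

    def mask_array(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m


def average_echoes(e3: VolumetricImage, e4: VolumetricImage) -> VolumetricImage:
    """Voxelwise arithmetic mean of two echo images (SNR gain of √2)."""
    e3.require_same_grid(e4)
    return VolumetricImage(
        data=(e3.data.astype(float) + e4.data.astype(float)) / 2.0, affine=e3.affine
    )


def normalize_roi(img: VolumetricImage, roi: RoiBox) -> VolumetricImage:
    """Z-score intensities over the ROI box; zero outside it.

    Normalization uses the population SD of the ROI voxels, so the
    output ROI has mean 0 and SD 1 exactly — the convention under which
    a delineation viewer window of [−2, +2] means ±2 SD.
    """
    roi.validate_in(img)
    patch = img.data[roi.slices].astype(float)
    sd = float(patch.std())
    if sd == 0.0:
        raise DegenerateRoiError("ROI intensities are constant; z-score undefined")
    out = np.zeros(img.grid_shape, dtype=float)
    out[roi.slices] = (patch - patch.mean()) / sd
    return VolumetricImage(data=out, affine=img.affine)


def fuse_contrast(
    t1_norm: VolumetricImage, t2s_norm: VolumetricImage
) -> VolumetricImage:
    """Voxelwise sum of the two ROI-normalized sections."""
    t1_norm.require_same_grid(t2s_norm)
    return VolumetricImage(
        data=t1_norm.data.astype(float) + t2s_norm.data.astype(float),
        affine=t1_norm.affine,
    )


def midbrain_contrast(
    t1w: VolumetricImage,
    echo3: VolumetricImage,
    echo4: VolumetricImage,
    roi: RoiBox,
) -> VolumetricImage:
    """Full fusion chain: average echoes, z-score both modalities over
    the midbrain box, and sum — the image used for manual delineation."""
    t2s = average_echoes(echo3, echo4)
    return fuse_contrast(normalize_roi(t1w, roi), normalize_roi(t2s, roi))
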