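"""Probabilistic atlas construction, thresholding, and spatial statistics.

The atlas is the voxelwise mean of per-subject binary masks in a shared
space: each voxel's value is the fraction of subjects whose mask
contains it, so values are quantized to {0, 1/n, ..., 1}. Thresholding
at t retains voxels shared by at least a fraction t of subjects
(inclusive); t = 0 means the unthresholded support. The weighted atlas
volume is conserved: it equals the mean contributing-mask volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import (
    BinaryMask,
    GeometryError,
    VolumetricImage,
    voxel_volume,
    world_coords,
)

__all__ = [
    "ProbabilisticAtlas",
    "ComStats",
    "build_atlas",
    "threshold_atlas",
    "volume",
    "threshold_volume_curve",
    "center_of_mass",
    "com_dispersion",
]


@dataclass
class ProbabilisticAtlas(VolumetricImage):
    """VolumetricImage with values in [0, 1]: per-voxel fraction of
    contributing subjects whose mask includes the voxel."""

    n_subjects: int = 0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        # float64 in memory so probability-mass identities hold to 1e-9;
        # write_volume stores atlases as float32 on disk
        self.data = self.data.astype(np.float64)
        if self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6:
            raise ValueError("atlas values must lie in [0, 1]")

    @property
    def support(self) -> BinaryMask:
        """Voxels with strictly positive probability (unthresholded extent)."""
        return BinaryMask(data=self.data > 0, affine=self.affine)


@dataclass(frozen=True)
class ComStats:
    """Cohort center-of-mass dispersion in world mm.

    ``mean_signed_deviation`` is the per-axis average of signed
    deviations from the cohort-mean CoM — identically zero up to float
    rounding, the arithmetic identity behind a reported dispersion
    center of "< 0.001 mm". ``sd`` is the per-axis population SD.
    """

    per_mask_com: np.ndarray  # (n, 3) mm
    mean_com: np.ndarray  # (3,) mm
    mean_signed_deviation: np.ndarray  # (3,) mm, ~0
    sd: np.ndarray  # (3,) mm

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_mask_com, columns=["x_mm", "y_mm", "z_mm"])
        df.index.name = "mask"
        return df


def build_atlas(
    masks: list[BinaryMask], provenance: list[str] | None = None
) -> ProbabilisticAtlas:
    """Voxelwise arithmetic mean of >= 2 binary masks on one shared grid."""
    if len(masks) < 2:
        raise ValueError(f"atlas needs >= 2 masks, got {len(masks)}")
    ref = masks[0]
    for m in masks[1:]:
        ref.require_same_grid(m)
    stack = np.stack([m.data for m in masks]).astype(np.float64)
    return ProbabilisticAtlas(
        data=stack.mean(axis=0),
        affine=ref.affine,
        n_subjects=len(masks),
        provenance=list(provenance or []),
    )


def threshold_atlas(atlas: ProbabilisticAtlas, t: float) -> BinaryMask:
    """Voxels with probability >= t (t > 0), or > 0 when t = 0
    ("unthresholded"): a threshold of 0.5 excludes voxels not shared by
    at least 50% of subjects."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    if t == 0.0:
        return atlas.support
    # tolerance absorbs float32 storage of exact fractions k/n
    return BinaryMask(data=atlas.data >= t - 1e-6, affine=atlas.affine)


def volume(
    x: BinaryMask | ProbabilisticAtlas, weighted: bool = False
) -> float:
    """Volume in mm³: nonzero-voxel count x voxel volume, or, weighted,
    the probability-mass volume (sum of values x voxel volume)."""
    vv = voxel_volume(x)
    if weighted:
        return float(x.data.astype(np.float64).sum()) * vv
    return float(np.count_nonzero(x.data)) * vv


def threshold_volume_curve(
    atlas: ProbabilisticAtlas, thresholds: list[float]
) -> pd.DataFrame:
    """Atlas volume at each threshold; non-increasing in the threshold."""
    ts = list(thresholds)
    if sorted(set(ts)) != ts:
        raise ValueError("thresholds must be sorted and unique")
    rows = [
        {"threshold": t, "volume_mm3": volume(threshold_atlas(atlas, t))} for t in ts
    ]
    return pd.DataFrame(rows)


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of the mask's voxel-center world coordinates (mm)."""
    if mask.is_empty:
        raise ValueError("center of mass undefined for an empty mask")
    idx = np.argwhere(mask.data)
    return world_coords(mask, idx).mean(axis=0)


def com_dispersion(masks: list[BinaryMask]) -> ComStats:
    """Per-axis signed deviations of each mask's CoM from the cohort
    mean, their mean (an analytic zero) and population SD."""
    if len(masks) < 2:
        raise ValueError("dispersion needs >= 2 masks")
    ref = masks[0]
    for m in masks[1:]:
        if not np.allclose(ref.affine, m.affine):
            raise GeometryError("masks are not in one shared space")
    coms = np.stack([center_of_mass(m) for m in masks])
    mean = coms.mean(axis=0)
    dev = coms - mean
    return ComStats(
        per_mask_com=coms,
        mean_com=mean,
        mean_signed_deviation=dev.mean(axis=0),
        sd=dev.std(axis=0),  # population convention
    )
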