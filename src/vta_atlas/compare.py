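"""Thresholded cross-atlas comparison.

Brings two probabilistic atlases onto one grid by affine-grid
resampling (deformable registration is delegated: the module consumes
atlases already expressed in a common standard space), thresholds both,
and tabulates relative volume difference and (dilated) Dice overlap per
threshold and hemisphere side.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import ProbabilisticAtlas, threshold_atlas, volume
from .image_io import BinaryMask, VolumetricImage, world_coords
from .metrics import UndefinedMetricError, dice, dilated_dice

__all__ = [
    "CoverageWarning",
    "resample_to_grid",
    "relative_volume_difference",
    "split_sides",
    "compare_atlases",
]

_ORDER = {"nearest": 0, "linear": 1}


class CoverageWarning(UserWarning):
    """The reference grid is not fully covered by the source atlas."""


def resample_to_grid(
    atlas: ProbabilisticAtlas,
    reference: VolumetricImage,
    method: str = "linear",
) -> ProbabilisticAtlas:
    """Sample the atlas on the reference grid through the two affines.

    Each reference voxel center is mapped to world mm and back into the
    atlas's voxel space; values are interpolated (``nearest`` preserves
    binary-ness, ``linear`` preserves the value range) and clipped to
    [0, 1]. A :class:`CoverageWarning` reports the overlap fraction when
    part of the reference grid falls outside the atlas's field of view.
    """
    if method not in _ORDER:
        raise ValueError(f"method must be one of {sorted(_ORDER)}, got {method!r}")
    out = _map_resample(atlas, reference, _ORDER[method])
    covered = _coverage_fraction(atlas, reference)
    if covered < 1.0 - 1e-9:
        warnings.warn(
            f"reference grid only {covered:.1%} covered by atlas field of view",
            CoverageWarning,
            stacklevel=2,
        )
    return ProbabilisticAtlas(
        data=np.clip(out, 0.0, 1.0),
        affine=reference.affine,
        n_subjects=atlas.n_subjects,
        provenance=list(atlas.provenance),
    )


def _map_resample(
    atlas: ProbabilisticAtlas, reference: VolumetricImage, order: int
) -> np.ndarray:
    M = np.linalg.inv(atlas.affine) @ reference.affine
    idx = np.indices(reference.grid_shape, dtype=float).reshape(3, -1)
    src = M[:3, :3] @ idx + M[:3, 3:4]
    out = ndimage.map_coordinates(
        atlas.data.astype(np.float64),
        src,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return out.reshape(reference.grid_shape)


def _coverage_fraction(
    atlas: ProbabilisticAtlas, reference: VolumetricImage
) -> float:
    M = np.linalg.inv(atlas.affine) @ reference.affine
    idx = np.indices(reference.grid_shape, dtype=float).reshape(3, -1)
    src = M[:3, :3] @ idx + M[:3, 3:4]
    hi = (np.asarray(atlas.grid_shape) - 1)[:, None]
    inside = ((src >= -0.5) & (src <= hi + 0.5)).all(axis=0)
    return float(inside.mean())


def relative_volume_difference(
    a: BinaryMask, b: BinaryMask, variant: str = "reference"
) -> float:
    """|V_a − V_b| / V_b with b the reference (``variant="reference"``),
    or |V_a − V_b| / mean(V_a, V_b) (``variant="symmetric"``); 0 iff
    the volumes are equal."""
    va, vb = volume(a), volume(b)
    if variant == "reference":
        if vb == 0:
            raise UndefinedMetricError("reference mask has zero volume")
        return abs(va - vb) / vb
    if variant == "symmetric":
        if va + vb == 0:
            raise UndefinedMetricError("both masks have zero volume")
        return abs(va - vb) / ((va + vb) / 2.0)
    raise ValueError(f"unknown volume-difference variant {variant!r}")


def split_sides(mask: BinaryMask) -> dict[str, BinaryMask]:
    """Split a bilateral mask into left/right by the world-x sign of each
    connected component's center of mass (x < 0 is left in RAS-like
    spaces such as MNI)."""
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), bool))
    left = np.zeros(mask.grid_shape, dtype=bool)
    right = np.zeros(mask.grid_shape, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        com_vox = np.argwhere(comp).mean(axis=0)
        x_mm = world_coords(mask, com_vox[None, :])[0, 0]
        (left if x_mm < 0 else right)[comp] = True
    return {
        "left": BinaryMask(data=left, affine=mask.affine),
        "right": BinaryMask(data=right, affine=mask.affine),
    }


def compare_atlases(
    a: ProbabilisticAtlas,
    b: ProbabilisticAtlas,
    thresholds: tuple[float, ...] = (0.0, 0.25, 0.5),
    sides: tuple[str, ...] = ("both",),
    connectivity: int = 6,
    vd_variant: str = "reference",
) -> pd.DataFrame:
    """Per (threshold, side): relative volume difference of the
    thresholded atlases (b is the reference) plus Dice and dilated-Dice
    overlap. ``sides`` may be ``("both",)`` to compare whole atlases or
    ``("left", "right")`` to split components by world-x sign. Rows with
    an empty thresholded mask are flagged, not fatal.
    """
    if not a.same_grid(b):
        b = resample_to_grid(b, a, method="linear")
    rows = []
    for t in thresholds:
        ma, mb = threshold_atlas(a, t), threshold_atlas(b, t)
        parts_a = {"both": ma} if sides == ("both",) else split_sides(ma)
        parts_b = {"both": mb} if sides == ("both",) else split_sides(mb)
        for side in sides:
            sa, sb = parts_a[side], parts_b[side]
            row: dict[str, object] = {"threshold": t, "side": side}
            if sa.is_empty or sb.is_empty:
                row.update(
                    volume_difference=np.nan,
                    dice_overlap=np.nan,
                    dilated_dice_overlap=np.nan,
                    empty=True,
                )
            else:
                row.update(
                    volume_difference=relative_volume_difference(
                        sa, sb, variant=vd_variant
                    ),
                    dice_overlap=dice(sa, sb),
                    dilated_dice_overlap=dilated_dice(
                        sa, sb, connectivity=connectivity
                    ),
                    empty=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)
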