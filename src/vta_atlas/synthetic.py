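"""Synthetic midbrain cohort generator.

Produces phantom subjects — a T1-weighted image with a dark CSF-like
tube (fourth-ventricle analogue), two T2*-weighted echo images with
hyperintense landmark blobs (red nucleus / substantia nigra analogues)
and Rician-like noise, a ground-truth target structure, and per-rater
masks that disagree only by one-voxel boundary jitter — so that every
downstream stage (contrast fusion, reliability metrics, atlas building)
is testable without any real data.

The target structure is an ellipsoid core with thin antipodal
protrusions, giving the high surface/volume ratio characteristic of
small arborized midbrain nuclei (~140 mm³). Cohorts place the structure
at per-subject Gaussian offsets around the midbrain-box center, with
per-axis dispersion matching the mm-scale scatter of individual-subject
centers of mass reported for such structures in standard space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contrast import RoiBox
from .image_io import BinaryMask, VolumetricImage

__all__ = [
    "CohortSpec",
    "SubjectScan",
    "GenerationError",
    "make_phantom_subject",
    "make_cohort",
    "jitter_mask",
    "synthesize_structure",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face (6-) connectivity


class GenerationError(RuntimeError):
    """Requested phantom cannot be generated on the given grid."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the study conditions: 27 subjects, 2 raters,
    0.7 mm isotropic grid, a 23 x 23 x 44-voxel midbrain box
    (1.6 x 1.6 x 3.08 cm³), a target structure of 140 ± 38 mm³, and
    per-axis center-of-mass dispersion of (0.8, 1.4, 2.2) mm.
    ``jitter_p`` is the probability that each boundary-shell voxel flips
    in a rater's mask; 0.5 makes every boundary voxel maximally
    uncertain, the simplest rendering of rater differences that stay
    within one voxel of each other.
    """

    n_subjects: int = 27
    n_raters: int = 2
    grid_shape: tuple[int, int, int] = (33, 33, 54)
    voxel_size_mm: float = 0.7
    box_corner: tuple[int, int, int] = (5, 5, 5)
    box_size: tuple[int, int, int] = (23, 23, 44)
    target_volume_mean_mm3: float = 140.0
    target_volume_sd_mm3: float = 38.0
    jitter_p: float = 0.5
    com_sd_mm: tuple[float, float, float] = (0.8, 1.4, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_raters < 1:
            raise ValueError("n_subjects and n_raters must be >= 1")
        if not 0.0 <= self.jitter_p <= 1.0:
            raise ValueError(f"jitter_p must be in [0, 1], got {self.jitter_p}")
        if self.target_volume_sd_mm3 < 0 or any(s < 0 for s in self.com_sd_mm):
            raise ValueError("standard deviations must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def affine(self) -> np.ndarray:
        # grid centered on the world origin, mimicking a standard space
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -0.5 * (np.asarray(self.grid_shape) - 1) * self.voxel_size_mm
        return aff

    @property
    def midbrain_box(self) -> RoiBox:
        return RoiBox(corner=self.box_corner, size=self.box_size)

    def as_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "box_corner": list(self.box_corner),
            "box_size": list(self.box_size),
            "target_volume_mean_mm3": self.target_volume_mean_mm3,
            "target_volume_sd_mm3": self.target_volume_sd_mm3,
            "jitter_p": self.jitter_p,
            "com_sd_mm": list(self.com_sd_mm),
            "seed": self.seed,
        }


@dataclass
class SubjectScan:
    """One phantom subject: images, ground truth, and rater masks."""

    t1w: VolumetricImage
    echo3: VolumetricImage
    echo4: VolumetricImage
    truth_mask: BinaryMask
    rater_masks: list[BinaryMask] = field(default_factory=list)
    midbrain_box: RoiBox | None = None


def _boundary_shell(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inner and outer one-voxel boundary shells (6-connectivity)."""
    m = mask.astype(bool)
    outer = ndimage.binary_dilation(m, structure=_STRUCT6) & ~m
    inner = m & ~ndimage.binary_erosion(m, structure=_STRUCT6)
    return inner, outer


def jitter_mask(
    mask: BinaryMask, jitter_p: float, seed: int | np.random.Generator
) -> BinaryMask:
    """Flip each one-voxel boundary-shell voxel independently with
    probability ``jitter_p``; the interior and far exterior are untouched.

    By construction the output always contains the 6-connectivity
    erosion of the input and lies within its one-voxel dilation.
    """
    if not 0.0 <= jitter_p <= 1.0:
        raise ValueError(f"jitter_p must be in [0, 1], got {jitter_p}")
    if mask.is_empty:
        raise ValueError("cannot jitter an empty mask")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    inner, outer = _boundary_shell(mask.data)
    out = mask.data.astype(bool).copy()
    flips = rng.random(mask.grid_shape) < jitter_p
    out[inner & flips] = False
    out[outer & flips] = True
    return BinaryMask(data=out, affine=mask.affine)


def _implicit_structure(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
    protrusions: list[tuple[np.ndarray, float, float]],
    scale: float,
) -> np.ndarray:
    """Union of a scaled ellipsoid and thin cylindrical protrusions."""
    grid = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"),
        axis=-1,
    )
    rel = grid - center
    q = ((rel / (semi_axes * scale)) ** 2).sum(axis=-1)
    inside = q <= 1.0
    for direction, length, radius in protrusions:
        t = rel @ direction  # axial coordinate along the protrusion
        radial = np.linalg.norm(rel - t[..., None] * direction, axis=-1)
        inside |= (t >= 0) & (t <= length * scale) & (radial <= radius)
    return inside


def synthesize_structure(
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    center_vox: np.ndarray,
    target_voxels: int,
    rng: np.random.Generator,
    box: RoiBox | None = None,
    n_protrusions: int | None = None,
) -> BinaryMask:
    """Build an arborized target structure of approximately
    ``target_voxels`` voxels, clipped to ``box`` when given.

    The core is an ellipsoid elongated along z; 2 or 4 thin protrusions
    are added as antipodal pairs (keeping the center of mass near
    ``center_vox``), and a global scale factor is bisected so that the
    in-box voxel count matches the target. ``n_protrusions=0`` yields a
    plain ellipsoid — useful as a low-surface-ratio comparison shape.
    """
    if n_protrusions is None:
        n_protrusions = int(rng.choice([2, 4]))
    if n_protrusions % 2 or n_protrusions < 0:
        raise ValueError("n_protrusions must be a non-negative even number")
    if target_voxels < 8:
        raise GenerationError(f"target of {target_voxels} voxels is too small")

    # base ellipsoid: elongated along z, mildly randomized aspect
    base = np.array([1.0, 0.9, 1.7]) * rng.uniform(0.9, 1.1, size=3)
    protrusions: list[tuple[np.ndarray, float, float]] = []
    for _ in range(n_protrusions // 2):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(3.0, 5.0) + base.max()  # beyond the core surface
        # antipodal pairs of equal length keep the shape centro-symmetric,
        # so the center of mass stays at the requested center
        protrusions.append((d, length, 1.1))
        protrusions.append((-d, length, 1.1))

    box_mask = box.mask_array(grid_shape) if box is not None else None

    def count(scale: float) -> int:
        m = _implicit_structure(grid_shape, center_vox, base, protrusions, scale)
        if box_mask is not None:
            m &= box_mask
        return int(m.sum())

    lo, hi = 0.3, 8.0
    if count(hi) < target_voxels:
        raise GenerationError(
            f"target volume of {target_voxels} voxels not achievable on grid "
            f"{grid_shape} (box-limited maximum {count(hi)})"
        )
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_voxels:
            lo = mid
        else:
            hi = mid
    m = _implicit_structure(grid_shape, center_vox, base, protrusions, hi)
    if box_mask is not None:
        m &= box_mask
    if not m.any():
        raise GenerationError("generated structure is empty")
    return BinaryMask(data=m, affine=affine)


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex Gaussian around the signal (MR magnitude noise)."""
    re = signal + rng.normal(scale=sigma, size=signal.shape)
    im = rng.normal(scale=sigma, size=signal.shape)
    return np.hypot(re, im)


def _subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    # entropy-pool seeding is portable across platforms and word orders
    return np.random.default_rng([spec.seed, subject_index])


def make_phantom_subject(spec: CohortSpec, subject_index: int = 0) -> SubjectScan:
    """Generate one phantom subject deterministically from (spec.seed,
    subject_index).

    The truth structure's volume is drawn from the spec's Normal
    distribution (truncated below at 40 mm³); its center is displaced
    from the box center by Gaussian per-axis offsets with the spec's
    mm SDs (clipped at ±2.5 SD so the structure stays inside the box).
    Rater masks are independent boundary jitters of the truth.
    """
    rng = _subject_rng(spec, subject_index)
    affine = spec.affine
    box = spec.midbrain_box
    box.validate_in(VolumetricImage(np.zeros(spec.grid_shape), affine))
    vox_vol = spec.voxel_size_mm**3

    vol_mm3 = max(
        40.0,
        rng.normal(spec.target_volume_mean_mm3, spec.target_volume_sd_mm3),
    )
    target_voxels = max(8, int(round(vol_mm3 / vox_vol)))

    sd = np.asarray(spec.com_sd_mm, dtype=float)
    offset_mm = np.clip(rng.normal(scale=sd, size=3) if sd.any() else np.zeros(3),
                        -2.5 * sd, 2.5 * sd)
    box_center = np.asarray(box.corner) + (np.asarray(box.size) - 1) / 2.0
    center_vox = box_center + offset_mm / spec.voxel_size_mm

    truth = synthesize_structure(
        spec.grid_shape, affine, center_vox, target_voxels, rng, box=box
    )

    rater_masks = [
        jitter_mask(truth, spec.jitter_p, rng) for _ in range(spec.n_raters)
    ]

    # --- phantom images -------------------------------------------------
    shape = spec.grid_shape
    t1_signal = np.full(shape, 1000.0)
    # dark CSF-like tube along z at the ventro-medial box edge
    gx, gy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tube_center = (box.corner[0] + 2.0, box.corner[1] + box.size[1] - 3.0)
    tube = (gx - tube_center[0]) ** 2 + (gy - tube_center[1]) ** 2 <= 2.5**2
    t1_signal[tube, :] = 250.0
    t1w = VolumetricImage(
        data=t1_signal + rng.normal(scale=40.0, size=shape), affine=affine
    )

    echo_signal = np.full(shape, 500.0)
    # two hyperintense landmark blobs flanking the structure (RN/SN analogues)
    zz = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"),
        axis=-1,
    )
    for blob_offset, radius in (((5.0, 3.0, -4.0), 3.0), ((-5.0, -2.0, 2.0), 3.5)):
        c = center_vox + np.asarray(blob_offset)
        blob = ((zz - c) ** 2).sum(axis=-1) <= radius**2
        echo_signal[blob] = 1400.0
    echo_signal[truth.data.astype(bool)] = 750.0  # structure mildly hyperintense
    echo3 = VolumetricImage(data=_rician(echo_signal, 60.0, rng), affine=affine)
    echo4 = VolumetricImage(data=_rician(echo_signal * 0.85, 60.0, rng), affine=affine)

    return SubjectScan(
        t1w=t1w,
        echo3=echo3,
        echo4=echo4,
        truth_mask=truth,
        rater_masks=rater_masks,
        midbrain_box=box,
    )


def make_cohort(spec: CohortSpec) -> list[SubjectScan]:
    """Generate the full cohort on one shared grid (the standard space)."""
    return [make_phantom_subject(spec, i) for i in range(spec.n_subjects)]
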