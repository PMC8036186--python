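# Methods

## Problem and scope

`vta_atlas` implements the computational chain by which a probabilistic
atlas of a small midbrain nucleus — the ventral tegmental area (VTA) is
the motivating case — is constructed and validated from per-subject
manual delineations:

1. **Contrast fusion** of the three MRI modalities used for
   delineation (a T1-weighted image and the 3rd/4th echoes of a
   T2\*-weighted multi-echo acquisition) into a single "midbrain
   contrast" image.
2. **Inter-rater agreement** between two raters' binary masks: Dice,
   dilated Dice, and Hausdorff distance.
3. **Probabilistic aggregation** of per-subject conjunction masks into
   an atlas, with threshold–volume analysis and center-of-mass (CoM)
   statistics.
4. **Cross-atlas comparison** of two probabilistic atlases after
   affine-grid resampling.

Acquisition, skull stripping, and linear/nonlinear registration to a
standard space are out of scope: the toolkit assumes masks already live
on one shared grid, and performs only affine-grid resampling when
comparing atlases on different grids. Individual-subject masks of the
motivating study are not public, so a synthetic cohort generator
provides study-scale inputs for every stage.

## Models and procedures

### Contrast fusion

The delineation image is built in three steps on a pre-defined midbrain
box (default 23 × 23 × 44 voxels ≈ 1.6 × 1.6 × 3.08 cm³ at 0.7 mm):
(1) voxelwise averaging of echoes 3 and 4 (noise SD falls by √2 for
independent equal-variance noise); (2) z-scoring of the averaged echo
and of the T1-weighted image over the box voxels; (3) voxelwise
summation of the two normalized sections. Z-scoring uses the
*population* SD, so the box has mean 0 and SD 1 exactly; this is the
convention under which a delineation viewer window of [−2, +2] reads as
±2 SD. Whether the original protocol used population or sample SD is
indeterminate; the two differ by a constant factor that cannot change
any delineation decision. A constant-intensity box is a degenerate
input and raises rather than dividing by zero.

### Agreement metrics

For rater masks A and B on one grid:

- **Conjunction** A ∧ B (voxelwise AND) is the segmentation unit that
  enters the atlas; an empty conjunction is legal and flagged, not
  fatal.
- **Dice** = 2|A∩B| / (|A|+|B|). Undefined (raises) when both masks
  are empty.
- **Dilated Dice** is an overlap score that forgives single-voxel
  boundary offsets — the appropriate reliability metric for small
  structures whose voxels are mostly surface voxels. Two variants are
  implemented:
  - `cross` (default): (|A∩dil(B)| + |B∩dil(A)|) / (|A|+|B|), each
    original mask intersected with the *other's* one-voxel dilation.
    Because A∩dil(B) ⊇ A∩B, this variant is **provably ≥ classical
    Dice** for every mask pair.
  - `dilated`: the Dice formula applied to the two dilated masks.
    Equally forgiving of coherent one-voxel offsets, but on sparse,
    isolated boundary flips of thin (one-voxel-thick) structures the
    dilation amplifies each disagreement into its whole neighborhood,
    and the value can fall marginally (~10⁻³) below classical Dice.
    The dominance guarantee is why `cross` is the default; `dilated`
    remains selectable (`--dd-variant dilated`).
  "One voxel" does not by itself fix a 3-D neighborhood; the default
  structuring element is 6-connectivity (face neighbors), with 18 and
  26 selectable.
- **Hausdorff distance** is the classical maximum (not a percentile):
  max over both masks of the distance from each member voxel center to
  the nearest voxel center of the other mask. It is computed with a
  Euclidean distance transform of each mask's complement (exact on a
  regular grid; an all-pairs brute-force oracle confirms equality in
  the tests). Voxel-unit distances are Euclidean in index space; mm
  distances use the voxel spacing from the affine. On an isotropic grid
  mm = voxels × voxel size exactly; on anisotropic grids the voxel-unit
  number is not physically meaningful, a warning is emitted, and the mm
  value (distance transform with per-axis sampling) is authoritative.

### Atlas construction and statistics

The probabilistic atlas is the voxelwise arithmetic mean of n
per-subject binary masks (the per-subject conjunction of the two
raters, by default): each value is the fraction of subjects whose mask
contains the voxel, quantized to {0, 1/n, …, 1}. Thresholding at t
keeps voxels with value ≥ t (inclusive — "shared by at least 50%"
includes exactly 50%); t = 0 denotes the support (all strictly positive
voxels). Two volume notions are exposed: unweighted (voxel count ×
voxel volume) and probability-weighted (sum of values × voxel volume).
The weighted atlas volume equals the mean contributing-mask volume
exactly (linearity of the mean); the atlas is held in float64 in memory
so this identity holds to 1e-9 mm³, and is written to disk as float32.

CoM of a mask is the unweighted mean of its voxel-center world
coordinates (not intensity-weighted). Cohort dispersion reports each
mask's CoM, the cohort mean, the per-axis mean *signed* deviation from
that mean — an analytic zero, reported as a computation sanity check —
and the per-axis SD. SDs use the population convention; which
convention the motivating study used is not recoverable, so its printed
SDs are treated as plausibility anchors only.

### Cross-atlas comparison

Two atlases are brought onto one grid by sampling one on the other's
grid through both affines (`map_coordinates`; nearest preserves
binary-ness, linear preserves the value range; values clipped to
[0, 1]); a coverage warning reports the fraction of the reference grid
inside the source field of view. At each threshold (default 0, 0.25,
0.5) and side, the table reports the relative volume difference
|V_a − V_b| / V_b (reference-normalized; a symmetric
|ΔV| / mean variant is selectable — published cross-atlas tables of
this kind print "volume difference" values whose unit is ambiguous, so
the normalization is a package choice, not a reproduction target),
plus Dice and dilated-Dice overlap. Hemisphere sides are split by
labeling connected components and assigning each by the world-x sign of
its CoM (x < 0 = left in RAS-like spaces).

## Synthetic cohort

The generator emulates the study conditions, not MR physics:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 27 | study cohort size |
| n_raters | 2 | delineation protocol |
| grid / voxel | 33 × 33 × 54 at 0.7 mm iso | midbrain box plus margin; acquired voxel size |
| midbrain box | 23 × 23 × 44 voxels | 1.6 × 1.6 × 3.08 cm³ |
| structure volume | Normal(140, 38) mm³, truncated at 40 | reported mask-volume distribution (mean 137.35, SD 38.27 mm³) |
| CoM dispersion | (0.8, 1.4, 2.2) mm per axis | reported per-axis CoM SDs (≈0.77–0.86, 1.42, 2.14–2.23 mm) |
| jitter_p | 0.5 | no rater-noise parameter is published; 0.5 makes each boundary voxel maximally uncertain, the simplest model of disagreement confined to one voxel |

The target structure is an ellipsoid core (elongated along z) with 2 or
4 thin cylindrical protrusions, giving the high surface/volume ratio of
an arborized nucleus. Protrusions are added in antipodal equal-length
pairs so the continuous shape is centro-symmetric about its center;
with zero dispersion the box center makes the voxelized set exactly
symmetric, so all subjects' CoMs coincide, and with Gaussian offsets
the realized CoM tracks the drawn center to sub-voxel error — which is
what makes CoM-SD parameter recovery testable at n = 27. A global scale
factor is bisected until the in-box voxel count matches the drawn
target volume; structures are clipped to the midbrain box so
containment is guaranteed by construction. Rater masks are independent
boundary jitters of the truth: only the one-voxel inner/outer boundary
shell (6-connectivity, matching the metric default) may flip, each
voxel independently with probability `jitter_p`, so every rater mask
contains the truth's erosion and lies within its dilation.

Phantom images carry the landmark geometry the delineation protocol
relies on — a dark CSF-like tube in the T1w image (fourth-ventricle
analogue) and two hyperintense blobs flanking the structure in the
echoes (red nucleus / substantia nigra analogues) — with Gaussian noise
on the T1w and Rician-like noise (magnitude of complex Gaussian) on the
echo magnitudes. No bias fields, motion, or sequence physics are
simulated. Passing tests therefore demonstrate the correctness of the
*computational chain* on masks with realistic size, shape, dispersion
and one-voxel rater disagreement; they say nothing about segmentation
difficulty on real MRI contrast.

All randomness flows through `numpy.random.default_rng` seeded with the
`(cohort seed, subject index)` pair, so cohorts are bit-reproducible
across platforms.

## Numerical choices and degenerate inputs

- Voxel indices are 0-based; affines map voxel centers (NIfTI
  convention). Voxel volume is |det| of the affine's 3×3 block, hence
  rotation-invariant. Voxel size is always read from the affine, never
  assumed constant.
- Header scl_slope/scl_inter are applied on read; a file requested as a
  mask whose values are not exactly {0, 1} after scaling is rejected
  with the offending values listed, never re-thresholded.
- Empty-vs-empty metric comparisons raise `UndefinedMetricError` rather
  than returning a conventional 0 or 1.
- Threshold comparison uses ≥ t − 1e-6 to absorb float32 round-trip of
  exact fractions k/n through NIfTI files.
- Atlas quantization (values × n integer) is asserted to 1e-6;
  probability-mass conservation to 1e-9 mm³.

## Problem sizes

Tests and the acceptance script run the full 27-subject cohort on the
33 × 33 × 54 grid (one cohort generation ≈ 15 s); the end-to-end demo
with reports completes in well under a minute without per-subject NIfTI
output and in ~1 min with it.

## Known limitations

- The jitter model perturbs only the one-voxel boundary shell; real
  raters occasionally disagree by more than one voxel (the motivating
  study's mean Hausdorff distance of ~8 voxels shows such excursions),
  so synthetic Hausdorff values are smaller than published ones. The
  published reliability means (Dice 0.56, dilated Dice 0.80) are
  plausibility anchors for the defaults, not reproduction targets.
- Deformable registration is never computed; cross-atlas comparison is
  meaningful only for atlases already in one standard space.
- Side splitting assumes the two hemispheric components are
  disconnected at the given threshold.
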