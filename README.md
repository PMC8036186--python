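# vta-atlas

A toolkit for building and validating **probabilistic atlases of small
midbrain nuclei** from per-subject manual delineations, with the
ventral tegmental area (VTA) — a ~140 mm³, sharply arborized,
border-poor dopaminergic structure — as the motivating case. It is
aimed at neuroimaging groups who have (or want to simulate) per-subject
binary masks in a shared space and need the full chain from delineation
contrast to published atlas numbers.

## What it computes

- **Midbrain contrast fusion** — the delineation image: average echoes
  3 and 4 of a T2\*-weighted multi-echo scan, z-score it and the
  T1-weighted image over a pre-defined midbrain box, and sum the two
  normalized sections.
- **Inter-rater reliability** for rater masks A, B:
  - Dice = 2|A∩B| / (|A|+|B|)
  - dilated Dice = (|A∩dil(B)| + |B∩dil(A)|) / (|A|+|B|) with dil(·)
    the one-voxel dilation — forgiving of single-voxel boundary
    offsets and provably ≥ Dice (a dice-of-dilations variant is also
    available)
  - Hausdorff distance = max{max_{x∈A} min_{y∈B} d(x,y),
    max_{y∈B} min_{x∈A} d(x,y)} in voxel units and mm
- **Probabilistic atlas** P(v) = (1/n) Σᵢ Mᵢ(v) over per-subject
  conjunction masks Mᵢ (voxels both raters selected), with inclusive
  thresholding (keep P ≥ t), threshold–volume curves, unweighted and
  probability-weighted volumes, and center-of-mass dispersion
  statistics.
- **Cross-atlas comparison**: affine-grid resampling onto one grid,
  then relative volume difference and (dilated) Dice per threshold and
  hemisphere.
- **Synthetic cohorts**: phantom subjects with an arborized target
  structure, landmark blobs, Rician-like echo noise and raters that
  disagree by one-voxel boundary jitter, so the whole chain runs
  without any data download.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from vta_atlas import (
    CohortSpec, make_cohort, conjunction, segmentation_report,
    build_atlas, threshold_volume_curve, com_dispersion, volume,
)

spec = CohortSpec(n_subjects=27, seed=42)     # 0.7 mm grid, 2 raters
cohort = make_cohort(spec)

rep = segmentation_report(*cohort[0].rater_masks)
print(f"subject 1: dice={rep.dice:.3f} dilated={rep.dilated_dice:.3f} "
      f"hausdorff={rep.hausdorff_vox:.2f} vox ({rep.hausdorff_mm:.2f} mm)")

conj = [conjunction(*s.rater_masks) for s in cohort]
atlas = build_atlas(conj)
print(f"atlas support volume: {volume(atlas.support):.2f} mm^3")
print(f"weighted volume:      {volume(atlas, weighted=True):.2f} mm^3 "
      f"(= mean mask volume {np.mean([volume(m) for m in conj]):.2f} mm^3)")
print(threshold_volume_curve(atlas, [0.0, 0.25, 0.5, 0.75, 1.0]).to_string(index=False))
stats = com_dispersion(conj)
print(f"CoM mean signed deviation (mm): {np.abs(stats.mean_signed_deviation).max():.2e}")
print(f"CoM per-axis SD (mm): {np.round(stats.sd, 2)}")
```

prints

```
subject 1: dice=0.679 dilated=0.980 hausdorff=1.41 vox (0.99 mm)
atlas support volume: 1224.51 mm^3
weighted volume:      106.10 mm^3 (= mean mask volume 106.10 mm^3)
 threshold  volume_mm3
      0.00    1224.510
      0.25      99.127
      0.50       5.145
      0.75       0.000
      1.00       0.000
CoM mean signed deviation (mm): 9.05e-17
CoM per-axis SD (mm): [0.79 1.12 2.41]
```

Reading the output: the two simulated raters agree closely in the Dice
sense and almost perfectly once one-voxel offsets are forgiven (the
dilated score), and their worst boundary disagreement is ~1 voxel. The
atlas support (every voxel any subject's conjunction mask touched) is
an order of magnitude larger than a single mask, and shrinks
monotonically as the probability threshold rises — at t = 0.75 no voxel
is shared by three quarters of the 27 subjects. The probability-
weighted volume equals the mean individual mask volume exactly
(conservation). The per-axis mean signed deviation of the individual
centers of mass from the cohort mean is zero to machine precision, and
the per-axis SDs recover the dispersion the cohort was generated with
(0.8, 1.4, 2.2 mm).

## Command line

```bash
vta-atlas simulate --n-subjects 27 --seed 42 --out cohort/
vta-atlas fuse --t1w T1w.nii.gz --echo3 e3.nii.gz --echo4 e4.nii.gz \
               --roi-corner 5,5,5 --roi-size 23,23,44 --out fused.nii.gz
vta-atlas reliability -a rater1.nii.gz -b rater2.nii.gz --out rel.tsv
vta-atlas build-atlas --manifest masks.csv --out-prefix atlas
vta-atlas compare atlas_a.nii.gz atlas_b.nii.gz --out cmp.tsv
vta-atlas demo --n-subjects 27 --seed 42 --out demo/   # the whole chain
```

Every output gets a JSON sidecar (tool version, config hash, input
checksums); deterministic stages reproduce bit-exactly from a sidecar's
config.

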