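import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vta_atlas.image_io import BinaryMask, GeometryError
from vta_atlas.metrics import (
    UndefinedMetricError,
    conjunction,
    dice,
    dilated_dice,
    hausdorff,
    segmentation_report,
)
from vta_atlas.synthetic import jitter_mask, synthesize_structure

from conftest import iso_affine, mask_from_voxels


def brute_force_hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """All-pairs oracle: max over both directions of min voxel distance."""
    pa = np.argwhere(a.data).astype(float)
    pb = np.argwhere(b.data).astype(float)
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_mask(rng, shape=(10, 10, 10), density=0.1) -> BinaryMask:
    data = rng.random(shape) < density
    if not data.any():
        data[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(data=data)


class TestConjunction:
    def test_idempotent(self, rng):
        m = random_mask(rng)
        assert np.array_equal(conjunction(m, m).data, m.data)

    def test_disjoint_masks_give_legal_empty(self):
        a = mask_from_voxels([(0, 0, 0)])
        b = mask_from_voxels([(5, 5, 5)])
        out = conjunction(a, b)
        assert out.is_empty

    def test_hand_count(self):
        a = mask_from_voxels([(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1)])
        b = mask_from_voxels(
            [(1, 1, 1), (1, 1, 2), (1, 2, 1), (3, 3, 3), (4, 4, 4), (5, 5, 5)]
        )
        assert conjunction(a, b).n_voxels == 3

    def test_grid_mismatch(self):
        a = mask_from_voxels([(0, 0, 0)])
        b = mask_from_voxels([(0, 0, 0)], affine=iso_affine(0.7))
        with pytest.raises(GeometryError):
            conjunction(a, b)


class TestDice:
    def test_identical_disjoint_and_hand_value(self):
        a = mask_from_voxels([(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1)])
        assert dice(a, a) == 1.0
        b = mask_from_voxels(
            [(1, 1, 1), (1, 1, 2), (1, 2, 1), (3, 3, 3), (4, 4, 4), (5, 5, 5)]
        )
        assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))
        disjoint = mask_from_voxels([(8, 8, 8)])
        assert dice(a, disjoint) == 0.0

    def test_both_empty_undefined(self):
        e = mask_from_voxels([])
        with pytest.raises(UndefinedMetricError):
            dice(e, e)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            assert dice(a, b) == dice(b, a)


class TestDilatedDice:
    def test_identical_masks(self):
        a = mask_from_voxels([(5, 5, 5), (5, 5, 6)])
        assert dilated_dice(a, a) == 1.0

    def test_single_voxel_offset_hand_enumeration(self):
        """Face-adjacent single voxels: under the dice-of-dilations
        variant each 6-dilation has 7 voxels and they share 2, so the
        value is 4/14; the default cross variant scores 1.0 (each voxel
        lies inside the other's dilation). Classical Dice is 0."""
        a = mask_from_voxels([(5, 5, 5)])
        b = mask_from_voxels([(6, 5, 5)])
        assert dice(a, b) == 0.0
        assert dilated_dice(a, b, connectivity=6, variant="dilated") == pytest.approx(4 / 14)
        assert dilated_dice(a, b, connectivity=6) == pytest.approx(1.0)

    def test_never_below_classical_on_jitter_fixtures(self, phantom_subject):
        truth = phantom_subject.truth_mask
        for p in (0.2, 0.5, 0.8, 1.0):
            for seed in (1, 2, 3):
                j = jitter_mask(truth, p, seed=seed)
                assert dilated_dice(truth, j) >= dice(truth, j)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_symmetry_all_connectivities(self, rng, connectivity):
        a, b = random_mask(rng), random_mask(rng)
        assert dilated_dice(a, b, connectivity=connectivity) == pytest.approx(
            dilated_dice(b, a, connectivity=connectivity)
        )

    def test_bad_connectivity_and_variant(self):
        a = mask_from_voxels([(0, 0, 0)])
        with pytest.raises(ValueError):
            dilated_dice(a, a, connectivity=4)
        with pytest.raises(ValueError):
            dilated_dice(a, a, variant="other")


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        vox, mm = hausdorff(m, m)
        assert vox == 0.0 and mm == 0.0

    def test_3_4_5_triangle(self):
        a = mask_from_voxels([(0, 0, 0)])
        b = mask_from_voxels([(3, 4, 0)])
        vox, mm = hausdorff(a, b)
        assert vox == pytest.approx(5.0)
        assert mm == pytest.approx(5.0)  # identity affine

    def test_mm_scales_with_isotropic_voxel_size(self):
        aff = iso_affine(0.7)
        a = mask_from_voxels([(0, 0, 0)], affine=aff)
        b = mask_from_voxels([(3, 4, 0)], affine=aff)
        vox, mm = hausdorff(a, b)
        assert mm == pytest.approx(vox * 0.7)

    def test_empty_mask_undefined(self):
        a = mask_from_voxels([(0, 0, 0)])
        with pytest.raises(UndefinedMetricError):
            hausdorff(a, mask_from_voxels([]))

    def test_distance_transform_equals_brute_force_oracle(self, rng):
        """Optimized path agrees exactly with the all-pairs oracle on
        random masks of up to ~300 voxels."""
        for density in (0.02, 0.1, 0.3):
            for _ in range(8):
                a = random_mask(rng, density=density)
                b = random_mask(rng, density=density)
                vox, _ = hausdorff(a, b)
                assert vox == pytest.approx(brute_force_hausdorff(a, b), abs=1e-9)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(10):
            a, b, c = (random_mask(rng) for _ in range(3))
            dab, _ = hausdorff(a, b)
            dba, _ = hausdorff(b, a)
            dac, _ = hausdorff(a, c)
            dcb, _ = hausdorff(c, b)
            assert dab == pytest.approx(dba)  # symmetry
            assert dab <= dac + dcb + 1e-9  # triangle inequality
        m = random_mask(rng)
        assert hausdorff(m, m)[0] == 0.0  # identity of indiscernibles

    def test_anisotropic_grid_warns_and_mm_authoritative(self):
        aff = np.diag([1.0, 1.0, 2.0, 1.0])
        a = mask_from_voxels([(0, 0, 0)], affine=aff)
        b = mask_from_voxels([(0, 0, 3)], affine=aff)
        with pytest.warns(UserWarning, match="anisotropic"):
            vox, mm = hausdorff(a, b)
        assert vox == pytest.approx(3.0)
        assert mm == pytest.approx(6.0)


class TestSegmentationReport:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        rep = segmentation_report(m, m)
        assert rep.dice == rep.dilated_dice == 1.0
        assert rep.hausdorff_vox == rep.hausdorff_mm == 0.0
        assert rep.vol_conj_mm3 == rep.vol_a_mm3 == rep.vol_b_mm3

    def test_fields_match_individual_ops(self, phantom_subject):
        a, b = phantom_subject.rater_masks
        rep = segmentation_report(a, b)
        assert rep.dice == dice(a, b)
        assert rep.dilated_dice == dilated_dice(a, b)
        assert rep.hausdorff_vox == hausdorff(a, b)[0]
        assert rep.vol_conj_mm3 <= min(rep.vol_a_mm3, rep.vol_b_mm3)

    def test_jittered_pair_dilated_exceeds_classical(self, phantom_subject):
        a = phantom_subject.truth_mask
        b = jitter_mask(a, 0.5, seed=11)
        rep = segmentation_report(a, b)
        assert rep.dice < rep.dilated_dice


class TestSurfaceVolumeEffect:
    def test_classical_dice_lower_for_arborized_shape(self):
        """At matched volume and jitter magnitude, the shape with the
        higher surface/volume ratio takes the larger classical-Dice hit."""
        rng = np.random.default_rng(77)
        shape, affine = (34, 34, 34), iso_affine(0.7)
        center = np.array([16.5, 16.5, 16.5])
        target = 400
        sphere = synthesize_structure(
            shape, affine, center, target, rng, n_protrusions=0
        )
        arbor = synthesize_structure(
            shape, affine, center, target, rng, n_protrusions=4
        )
        assert abs(sphere.n_voxels - arbor.n_voxels) <= 30  # matched volume

        def mean_dice(mask, seeds=range(6)):
            return np.mean(
                [dice(mask, jitter_mask(mask, 0.5, seed=s)) for s in seeds]
            )

        assert mean_dice(arbor) < mean_dice(sphere)
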