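"""Geometric metrics against brute-force oracles and hand constructions."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from psnseg.metrics import (
    deviation_map,
    dsc,
    evaluate_pair,
    hd95,
    msd,
    surface_distances,
    surface_voxels,
)

from conftest import random_blob


def brute_force_surface(mask):
    """Enumerate surface voxels by checking all six face-neighbours."""
    mask = mask.astype(bool)
    out = []
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= np.array(mask.shape)).any() or not mask[tuple(nb)]:
                    out.append(tuple(idx))
                    break
            else:
                continue
            break
    return sorted(out)


def brute_force_distances(a, b, spacing):
    """All-pairs symmetric surface distances (quadratic oracle)."""
    sa = np.array(brute_force_surface(a), dtype=float) * spacing
    sb = np.array(brute_force_surface(b), dtype=float) * spacing
    d = cdist(sa, sb)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


class TestDsc:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), np.uint8)
        b = np.zeros((6, 6, 6), np.uint8)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        assert dsc(a, b) == 0.0

    def test_shifted_cube_half_overlap(self):
        # 2x2x2 cubes shifted by one voxel: overlap 4 -> 2*4/(8+8) = 0.5
        a = np.zeros((6, 6, 6), np.uint8)
        b = np.zeros((6, 6, 6), np.uint8)
        a[2:4, 2:4, 2:4] = 1
        b[3:5, 2:4, 2:4] = 1
        assert dsc(a, b) == 0.5

    def test_symmetry_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_blob(rng), random_blob(rng)
            assert dsc(a, b) == dsc(b, a)
            assert 0.0 <= dsc(a, b) <= 1.0

    def test_both_empty_raises(self):
        z = np.zeros((4, 4, 4), np.uint8)
        with pytest.raises(ValueError):
            dsc(z, z)


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        assert surface_voxels(m).tolist() == [[2, 2, 2]]

    def test_solid_cube_surface_count(self):
        # 3x3x3 solid cube: all 27 voxels except the centre are surface
        m = np.zeros((7, 7, 7), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        assert len(surface_voxels(m)) == 26

    def test_grid_border_counts_as_outside(self):
        m = np.ones((3, 3, 3), np.uint8)
        assert len(surface_voxels(m)) == 27 - 1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = random_blob(rng)
            got = sorted(map(tuple, surface_voxels(m)))
            assert got == brute_force_surface(m)


class TestSurfaceDistances:
    def test_identical_all_zero(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        assert np.all(surface_distances(m, m, (1, 1, 1)) == 0.0)

    @pytest.mark.parametrize("spacing,expected", [((1, 1, 1), 3.0), ((2, 1, 1), 6.0)])
    def test_two_voxels_axis_apart(self, spacing, expected):
        a = np.zeros((8, 4, 4), np.uint8)
        b = np.zeros((8, 4, 4), np.uint8)
        a[1, 1, 1] = 1
        b[4, 1, 1] = 1  # 3 voxels apart along axis 0
        d = surface_distances(a, b, spacing)
        assert sorted(d.tolist()) == [expected, expected]

    def test_pooled_multiset_matches_brute_force(self):
        rng = np.random.default_rng(2)
        spacing = (1.0, 1.5, 2.0)
        for _ in range(25):
            a, b = random_blob(rng), random_blob(rng)
            got = np.sort(surface_distances(a, b, spacing))
            want = np.sort(brute_force_distances(a, b, spacing))
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestHd95Msd:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        assert hd95(m, m, (1, 1, 1)) == 0.0
        assert msd(m, m, (1, 1, 1)) == 0.0

    def test_parallel_plates(self):
        # two 1-voxel-thick parallel plates d mm apart: nearly every surface
        # voxel's nearest counterpart is directly across the gap
        a = np.zeros((9, 20, 20), np.uint8)
        b = np.zeros((9, 20, 20), np.uint8)
        a[2] = 1
        b[7] = 1  # 5 voxels * 1 mm apart
        assert msd(a, b, (1, 1, 1)) == pytest.approx(5.0, rel=0.02)

    def test_oracle_equivalence_random_masks(self):
        """hd95/msd agree with the all-pairs brute force to 1e-9 (100 trials)."""
        rng = np.random.default_rng(3)
        spacing = (2.0, 1.0, 1.0)
        for _ in range(100):
            shape = tuple(rng.integers(5, 13, size=3))
            a, b = random_blob(rng, shape), random_blob(rng, shape)
            pooled = brute_force_distances(a, b, spacing)
            assert abs(hd95(a, b, spacing) - np.percentile(pooled, 95)) < 1e-9
            assert abs(msd(a, b, spacing) - pooled.mean()) < 1e-9

    def test_hd95_bounded_by_max_distance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = random_blob(rng), random_blob(rng)
            d = surface_distances(a, b, (1, 1, 1))
            assert hd95(a, b, (1, 1, 1)) <= d.max() + 1e-12

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        a, b = random_blob(rng, (8, 8, 8)), random_blob(rng, (8, 8, 8))
        big_a = np.zeros((14, 14, 14), np.uint8)
        big_b = np.zeros((14, 14, 14), np.uint8)
        big_a[2:10, 2:10, 2:10] = a
        big_b[2:10, 2:10, 2:10] = b
        shift_a = np.roll(big_a, (3, 2, 1), axis=(0, 1, 2))
        shift_b = np.roll(big_b, (3, 2, 1), axis=(0, 1, 2))
        s = (1.0, 1.0, 2.0)
        assert dsc(big_a, big_b) == dsc(shift_a, shift_b)
        assert hd95(big_a, big_b, s) == pytest.approx(hd95(shift_a, shift_b, s))
        assert msd(big_a, big_b, s) == pytest.approx(msd(shift_a, shift_b, s))

    def test_msd_monotone_under_growing_offset(self):
        m = np.zeros((30, 8, 8), np.uint8)
        m[3:7, 2:6, 2:6] = 1
        prev = 0.0
        for off in range(0, 6):
            shifted = np.roll(m, off, axis=0)
            val = msd(m, shifted, (1, 1, 1)) if off else 0.0
            assert val >= prev - 1e-12
            prev = val


class TestDeviationMap:
    def test_identical_masks_all_zero(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        assert np.all(deviation_map(m, m, (1, 1, 1)) == 0.0)

    def test_dilation_gives_positive_erosion_negative(self):
        from scipy import ndimage

        ref = np.zeros((12, 12, 12), np.uint8)
        ref[3:9, 3:9, 3:9] = 1
        dil = ndimage.binary_dilation(ref).astype(np.uint8)
        ero = ndimage.binary_erosion(ref).astype(np.uint8)
        surf = surface_voxels(ref)
        dev_dil = deviation_map(ref, dil, (1, 1, 1))[tuple(surf.T)]
        dev_ero = deviation_map(ref, ero, (1, 1, 1))[tuple(surf.T)]
        assert np.all(dev_dil > 0)
        assert np.all(dev_ero < 0)

    def test_values_are_distances_to_predicted_surface(self):
        ref = np.zeros((10, 10, 10), np.uint8)
        ref[4:6, 4:6, 4:6] = 1
        pred = np.zeros((10, 10, 10), np.uint8)
        pred[3:7, 3:7, 3:7] = 1
        dev = deviation_map(ref, pred, (1, 1, 1))
        surf = surface_voxels(ref)
        vals = dev[tuple(surf.T)]
        assert np.all(vals > 0)  # prediction everywhere outside reference
        assert vals.max() <= np.sqrt(3) + 1e-9


def test_evaluate_pair_consistent_with_parts():
    rng = np.random.default_rng(6)
    a, b = random_blob(rng), random_blob(rng)
    s = (1.0, 1.0, 2.0)
    res = evaluate_pair(a, b, s)
    assert res.dsc == dsc(a, b)
    assert res.hd95_mm == pytest.approx(hd95(a, b, s))
    assert res.msd_mm == pytest.approx(msd(a, b, s))
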