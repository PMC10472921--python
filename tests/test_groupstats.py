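"""Group inference: t-maps, cluster mass, sign-flip FWE, FDR, Dice, spin."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastrosync import (GroupSample, SphereAnnotation, clusters_and_mass,
                        dice_similarity, fdr_bh, paired_t_map,
                        signflip_cluster_test, spin_test)
from gastrosync.groupstats import TMap, random_rotation, _rotate_labels
from gastrosync.synthetic import gen_sphere_annotation


def flood_fill_clusters(tvol, threshold, connectivity):
    """Brute-force BFS connected components oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    supra = tvol > threshold
    seen = np.zeros_like(supra)
    masses = []
    for idx in np.argwhere(supra):
        if seen[tuple(idx)]:
            continue
        mass = 0.0
        q = deque([tuple(idx)])
        seen[tuple(idx)] = True
        while q:
            p = q.popleft()
            mass += tvol[p]
            for off in offsets:
                nb = tuple(np.add(p, off))
                if all(0 <= nb[i] < tvol.shape[i] for i in range(3)) \
                        and supra[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        masses.append(mass)
    return sorted(masses)


class TestPairedT:
    def test_hand_computed_t(self):
        emp = np.array([[1.0], [2.0], [3.0]])
        t = paired_t_map(GroupSample(emp, np.zeros_like(emp)))
        assert t.t[0] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)
        assert t.df == 2

    def test_identical_maps_give_zero_t(self, rng):
        emp = rng.uniform(0, 1, (5, 10))
        t = paired_t_map(GroupSample(emp, emp.copy()))
        assert np.allclose(t.t, 0)

    def test_constant_difference_flags_zero_variance(self):
        emp = np.full((4, 3), 0.6)
        t = paired_t_map(GroupSample(emp, np.full((4, 3), 0.4)))
        assert t.zero_variance.all()
        assert np.allclose(t.t, 0)


class TestClusters:
    shape = (5, 5, 5)
    mask = np.ones(shape, dtype=bool)

    def tvec(self, entries):
        vol = np.zeros(self.shape)
        for pos, val in entries.items():
            vol[pos] = val
        return vol[self.mask]

    def test_two_face_adjacent_voxels_one_cluster_mass_six(self):
        cs = clusters_and_mass(self.tvec({(1, 1, 1): 3.0, (1, 1, 2): 3.0}),
                               self.shape, self.mask)
        assert cs.n_clusters == 1
        assert cs.masses[0] == pytest.approx(6.0)
        assert cs.sizes[0] == 2

    def test_diagonal_pair_depends_on_connectivity(self):
        entries = {(1, 1, 1): 3.0, (2, 2, 2): 3.0}
        c26 = clusters_and_mass(self.tvec(entries), self.shape, self.mask,
                                connectivity=26)
        c6 = clusters_and_mass(self.tvec(entries), self.shape, self.mask,
                               connectivity=6)
        assert c26.n_clusters == 1
        assert c6.n_clusters == 2

    def test_subthreshold_map_yields_empty_set(self):
        cs = clusters_and_mass(np.ones(self.mask.sum()), self.shape, self.mask)
        assert cs.n_clusters == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_maps(self, connectivity, rng):
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        for _ in range(10):
            tvol = rng.normal(1.5, 1.0, shape)
            cs = clusters_and_mass(tvol[mask], shape, mask, threshold=2.3,
                                   connectivity=connectivity)
            oracle = flood_fill_clusters(tvol, 2.3, connectivity)
            assert np.allclose(sorted(cs.masses), oracle)

    def test_raising_threshold_never_increases_mass(self, rng):
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        tvol = rng.normal(1.5, 1.0, shape)
        lo = clusters_and_mass(tvol[mask], shape, mask, threshold=2.0)
        hi = clusters_and_mass(tvol[mask], shape, mask, threshold=2.6)
        assert (hi.masses.max() if hi.n_clusters else 0) <= \
               (lo.masses.max() if lo.n_clusters else 0)


class TestSignFlip:
    shape = (6, 6, 6)
    mask = np.ones(shape, dtype=bool)

    def test_strong_common_effect_hits_p_floor(self, rng):
        n_perm = 400
        d = rng.normal(0, 0.01, (12, 216))
        d[:, :8] += 1.0  # strong effect in a compact block
        cs = signflip_cluster_test(GroupSample(d, np.zeros_like(d)),
                                   self.shape, self.mask, n_perm=n_perm, seed=1)
        assert cs.n_clusters >= 1
        # the floor 1/(1+n_perm), allowing for the rare random sign
        # pattern that reproduces the identity and ties the observed mass
        assert cs.p_fwe.min() <= 3 / (1 + n_perm)

    def test_single_subject_refused(self):
        small = np.zeros((2, 2, 2), dtype=bool) | True
        with pytest.raises(ValueError, match="two subjects"):
            signflip_cluster_test(GroupSample(np.ones((1, 8)), np.zeros((1, 8))),
                                  (2, 2, 2), small, n_perm=10)

    def test_pvalues_invariant_to_adjacency_preserving_voxel_permutation(self, rng):
        # reversing a grid axis permutes voxels consistently across all
        # subjects while preserving adjacency: identical p-values expected
        d = rng.normal(0.08, 0.2, (6, 216))
        vol = d.reshape(6, *self.shape)
        d_flipped = vol[:, ::-1, :, :].reshape(6, 216)
        cs1 = signflip_cluster_test(GroupSample(d, np.zeros_like(d)),
                                    self.shape, self.mask, n_perm=150, seed=7)
        cs2 = signflip_cluster_test(GroupSample(d_flipped, np.zeros_like(d)),
                                    self.shape, self.mask, n_perm=150, seed=7)
        assert np.allclose(np.sort(cs1.masses), np.sort(cs2.masses))
        assert np.allclose(np.sort(cs1.p_fwe), np.sort(cs2.p_fwe))


class TestFDR:
    def test_all_small_pvalues_rejected(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05).all()

    def test_step_up_rejects_none_when_first_fails(self):
        assert not fdr_bh([0.04, 0.5, 0.9], q=0.05).any()

    def test_zeros_always_rejected(self):
        assert fdr_bh([0.0, 0.0, 0.0]).all()

    def test_empty_input(self):
        assert fdr_bh([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_rejections_monotone_in_q(self, pvals):
        r_small = fdr_bh(pvals, q=0.01)
        r_large = fdr_bh(pvals, q=0.10)
        assert np.all(r_large | ~r_small)


class TestDice:
    def test_identical_nonempty_maps(self):
        a = np.array([True, True, False])
        assert dice_similarity(a, a) == 1.0

    def test_disjoint_maps(self):
        assert dice_similarity(np.array([True, False]),
                               np.array([False, True])) == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros(20, bool); a[:4] = True
        b = np.zeros(20, bool); b[2:8] = True
        assert dice_similarity(a, b) == pytest.approx(2 * 2 / (4 + 6))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_similarity(np.zeros(3, bool), np.zeros(4, bool))

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert dice_similarity(np.zeros(3, bool), np.zeros(3, bool)) == 0.0


class TestSpin:
    def test_identical_annotations_have_dice_one(self):
        fixed = gen_sphere_annotation(300, 0.2, seed=0)
        res = spin_test(fixed, fixed, n_perm=30, seed=1)
        assert res.dice_empirical == 1.0
        assert res.p <= 0.5

    def test_kdtree_and_exact_reassignment_agree(self, rng):
        _, ann = gen_sphere_annotation(300, 0.25, seed=2)
        for _ in range(5):
            R = random_rotation(rng)
            assert np.array_equal(_rotate_labels(ann, R, method="exact"),
                                  _rotate_labels(ann, R, method="kdtree"))

    def test_mirrored_rotation_preserves_bilateral_symmetry(self, rng):
        left, right = gen_sphere_annotation(400, 0.2, symmetry=True, seed=3)
        R = random_rotation(rng)
        M = np.diag([-1.0, 1.0, 1.0])
        lab_r = _rotate_labels(right, R, method="exact")
        lab_l = _rotate_labels(left, M @ R @ M, method="exact")
        assert np.array_equal(lab_l, lab_r)

    def test_label_count_roughly_conserved(self, rng):
        _, ann = gen_sphere_annotation(500, 0.2, seed=4)
        R = random_rotation(rng)
        rotated = _rotate_labels(ann, R, method="kdtree")
        assert abs(int(rotated.sum()) - int(ann.labels.sum())) <= 25

    def test_empty_target_rejected(self):
        fixed = gen_sphere_annotation(300, 0.2, seed=5)
        empty = gen_sphere_annotation(300, 0.0, seed=6)
        with pytest.raises(ValueError, match="no labelled"):
            spin_test(fixed, empty, n_perm=10, seed=0)

    def test_rotation_matrices_are_proper(self, rng):
        for _ in range(10):
            R = random_rotation(rng)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)
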