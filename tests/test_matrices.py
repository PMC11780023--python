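import numpy as np
import pytest

from dlradiomics.radiomics.matrices import (
    UNIQUE_DIRECTIONS_3D,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from .conftest import random_voi
from .oracles import brute_glcm, brute_gldm, brute_glrlm, brute_glszm, brute_ngtdm


def pad_to(m, shape):
    return np.pad(m, [(0, s - c) for s, c in zip(shape, m.shape)])


class TestGLCM:
    def test_hand_example_single_offset(self):
        lv = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        tm = compute_glcm(lv, directions=[(0, 1, 0)])
        assert np.allclose(tm.values, [[0.5, 0.25], [0.25, 0.0]])

    def test_uniform_voi(self):
        lv = np.ones((3, 3, 2), dtype=int)
        tm = compute_glcm(lv)
        assert np.allclose(tm.values, [[1.0]])

    def test_normalized_per_direction(self, rng):
        for _ in range(20):
            lv = random_voi(rng)
            tm = compute_glcm(lv)
            for mat in tm.per_direction:
                if mat.sum() > 0:  # directions with no pair stay all-zero
                    assert abs(mat.sum() - 1.0) < 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_glcm(np.zeros((2, 2, 2), dtype=int))

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            lv = random_voi(rng)
            ng = int(lv.max())
            for d in ((1, 0, 0), (0, 1, 0), (1, 1, -1)):
                got = compute_glcm(lv, directions=[d]).values
                ref = brute_glcm(lv, ng, d)
                if ref.sum() == 0:
                    assert np.allclose(got, 0.0)
                else:
                    assert np.allclose(got, ref / ref.sum())


class TestGLRLM:
    def test_hand_example(self):
        lv = np.array([1, 1, 2]).reshape(1, 3, 1)
        tm = compute_glrlm(lv, directions=[(0, 1, 0)])
        expected = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(tm.values, expected)

    def test_uniform_line_single_run(self):
        lv = np.ones((1, 6, 1), dtype=int)
        tm = compute_glrlm(lv, directions=[(0, 1, 0)])
        assert tm.values[0, 5] == 1.0 and tm.values.sum() == 1.0

    def test_runs_partition_voxels(self, rng):
        for _ in range(30):
            lv = random_voi(rng)
            tm = compute_glrlm(lv)
            j = np.arange(1, tm.per_direction.shape[2] + 1)
            for mat in tm.per_direction:
                assert np.isclose((mat * j).sum(), (lv > 0).sum())

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            lv = random_voi(rng)
            ng = int(lv.max())
            tm = compute_glrlm(lv)
            for mat, d in zip(tm.per_direction, UNIQUE_DIRECTIONS_3D):
                ref = brute_glrlm(lv, ng, d)
                shape = (ng, max(mat.shape[1], ref.shape[1]))
                assert np.allclose(pad_to(mat, shape), pad_to(ref, shape))


class TestGLSZM:
    def test_hand_example(self):
        lv = np.array([[1, 1], [2, 1]]).reshape(2, 2, 1)
        tm = compute_glszm(lv)
        assert tm.values[0, 2] == 1.0  # one zone of level 1, size 3
        assert tm.values[1, 0] == 1.0  # one zone of level 2, size 1
        assert tm.values.sum() == 2.0

    def test_checkerboard_diagonals_connect(self):
        # 26-connectivity joins the diagonal pairs: two zones of size 2
        lv = np.array([[1, 2], [2, 1]]).reshape(2, 2, 1)
        tm = compute_glszm(lv)
        ref = brute_glszm(lv, 2)
        assert np.allclose(tm.values, ref)
        assert tm.values[0, 1] == 1.0 and tm.values[1, 1] == 1.0

    def test_zones_partition_voxels(self, rng):
        for _ in range(30):
            lv = random_voi(rng)
            tm = compute_glszm(lv)
            s = np.arange(1, tm.values.shape[1] + 1)
            assert np.isclose((tm.values * s).sum(), (lv > 0).sum())

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            lv = random_voi(rng)
            ng = int(lv.max())
            got = compute_glszm(lv).values
            ref = brute_glszm(lv, ng)
            shape = (ng, max(got.shape[1], ref.shape[1]))
            assert np.allclose(pad_to(got, shape), pad_to(ref, shape))


class TestGLDM:
    def test_hand_example(self):
        lv = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        tm = compute_gldm(lv, alpha=0)
        assert tm.values[0, 2] == 3.0  # three level-1 voxels with 2 dependants
        assert tm.values[1, 0] == 1.0  # the level-2 voxel has none

    def test_uniform_voi_maximal_dependence(self):
        lv = np.ones((2, 2, 1), dtype=int)
        tm = compute_gldm(lv, alpha=0)
        assert tm.values[0, 3] == 4.0  # all voxels see all 3 neighbours
        assert tm.values.sum() == 4.0

    def test_counts_partition_voxels(self, rng):
        for _ in range(30):
            lv = random_voi(rng)
            assert np.isclose(compute_gldm(lv).values.sum(), (lv > 0).sum())

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            lv = random_voi(rng)
            ng = int(lv.max())
            for alpha in (0, 1):
                got = compute_gldm(lv, alpha=alpha).values
                ref = brute_gldm(lv, ng, alpha)
                shape = (ng, max(got.shape[1], ref.shape[1]))
                assert np.allclose(pad_to(got, shape), pad_to(ref, shape))


class TestNGTDM:
    def test_hand_example(self):
        lv = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        tm = compute_ngtdm(lv)
        n, p, s = tm.values[:, 0], tm.values[:, 1], tm.values[:, 2]
        assert n.tolist() == [3.0, 1.0]
        assert np.isclose(s[0], 1.0) and np.isclose(s[1], 1.0)
        assert np.isclose(p.sum(), 1.0)

    def test_uniform_voi_zero_differences(self):
        tm = compute_ngtdm(np.ones((3, 3, 3), dtype=int))
        assert np.allclose(tm.values[:, 2], 0.0)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(30):
            lv = random_voi(rng)
            tm = compute_ngtdm(lv)
            if tm.meta["n_valid"]:
                assert np.isclose(tm.values[:, 1].sum(), 1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            lv = random_voi(rng)
            ng = int(lv.max())
            got = compute_ngtdm(lv).values
            ref = brute_ngtdm(lv, ng)
            assert np.allclose(got, ref)
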