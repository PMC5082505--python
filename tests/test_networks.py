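"""Block means, segregation, lesion profiles, and the group contrast."""

import numpy as np
import pytest

import lesionconn as lc
from lesionconn.cohort import NetworkPartition


def _partition(labels, names, lesion=()):
    return NetworkPartition(labels=np.asarray(labels), names=tuple(names),
                            lesion=frozenset(lesion))


def _brute_force_blocks(conn, labels, K):
    out = np.full((K, K), np.nan)
    N = len(labels)
    for k in range(K):
        for l in range(K):
            vals = [conn[i, j] for i in range(N) for j in range(i + 1, N)
                    if {labels[i], labels[j]} == ({k, l} if k != l else {k})]
            if vals:
                out[k, l] = np.mean(vals)
    return out


class TestBlockMeans:
    def test_two_network_construction(self):
        labels = [0, 0, 0, 1, 1, 1]
        conn = np.full((6, 6), 0.2)
        same = np.equal.outer(labels, labels)
        conn[same] = 1.0
        np.fill_diagonal(conn, np.nan)
        block = lc.block_means(conn, _partition(labels, ("A", "B")))
        assert np.allclose(np.diag(block.values), 1.0)
        assert block.values[0, 1] == pytest.approx(0.2)

    def test_roi_permutation_invariance(self, rng):
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        conn = rng.standard_normal((10, 10))
        conn = (conn + conn.T) / 2
        np.fill_diagonal(conn, np.nan)
        part = _partition(labels, ("A", "B", "C"))
        base = lc.block_means(conn, part).values
        perm = rng.permutation(10)
        part_p = _partition(labels[perm], ("A", "B", "C"))
        permuted = lc.block_means(conn[np.ix_(perm, perm)], part_p).values
        assert np.allclose(base, permuted, equal_nan=True)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            N = int(rng.integers(6, 13))
            K = int(rng.integers(2, 4))
            labels = rng.integers(0, K, size=N)
            while len(np.unique(labels)) < K:
                labels = rng.integers(0, K, size=N)
            conn = rng.standard_normal((N, N))
            conn = (conn + conn.T) / 2
            np.fill_diagonal(conn, np.nan)
            part = _partition(labels, tuple(f"n{k}" for k in range(K)))
            got = lc.block_means(conn, part).values
            want = _brute_force_blocks(conn, labels, K)
            assert np.allclose(got, want, equal_nan=True)

    def test_singleton_network_diagonal_undefined(self, rng):
        conn = rng.standard_normal((4, 4))
        conn = (conn + conn.T) / 2
        part = _partition([0, 0, 0, 1], ("A", "B"))
        block = lc.block_means(conn, part)
        assert np.isnan(block.values[1, 1])

    def test_lesion_rois_excluded_from_host_network(self, rng):
        conn = rng.standard_normal((6, 6))
        conn = (conn + conn.T) / 2
        np.fill_diagonal(conn, np.nan)
        labels = [0, 0, 0, 1, 1, 1]
        with_lesion = lc.block_means(conn, _partition(labels, ("A", "B"),
                                                      lesion={0}))
        dropped = lc.block_means(conn[1:, 1:][:, :],
                                 _partition(labels[1:], ("A", "B")))
        assert np.allclose(with_lesion.values, dropped.values,
                           equal_nan=True)


class TestSegregation:
    def test_constructed_values(self):
        v = np.full((3, 3), 0.2)
        np.fill_diagonal(v, 1.0)
        assert lc.segregation(lc.BlockMatrix(v, ("a", "b", "c"))) == \
            pytest.approx(0.8)

    def test_uniform_matrix_gives_zero(self):
        v = np.full((4, 4), 0.7)
        assert lc.segregation(lc.BlockMatrix(v, tuple("abcd"))) == \
            pytest.approx(0.0)

    def test_translation_invariance(self, rng):
        v = rng.standard_normal((5, 5))
        v = (v + v.T) / 2
        b1 = lc.BlockMatrix(v, tuple("abcde"))
        b2 = lc.BlockMatrix(v + 3.3, tuple("abcde"))
        assert lc.segregation(b1) == pytest.approx(lc.segregation(b2),
                                                   abs=1e-10)

    def test_undefined_diagonal_raises(self):
        v = np.full((3, 3), 0.5)
        v[1, 1] = np.nan
        with pytest.raises(ValueError):
            lc.segregation(lc.BlockMatrix(v, ("a", "b", "c")))


class TestLesionProfile:
    def test_coupled_network_wins(self):
        conn = np.zeros((6, 6))
        conn[0, 1] = conn[1, 0] = conn[0, 2] = conn[2, 0] = 5.0
        part = _partition([0, 0, 0, 1, 1, 1], ("A", "B"), lesion={0})
        prof = lc.lesion_profile(conn, part)
        assert np.argmax(prof) == 0

    def test_zero_matrix_gives_zero_profile(self):
        part = _partition([0, 0, 1, 1], ("A", "B"), lesion={0})
        assert np.allclose(lc.lesion_profile(np.zeros((4, 4)), part), 0.0)

    def test_matches_exhaustive_enumeration(self, rng):
        N, K = 15, 3
        labels = rng.integers(0, K, size=N)
        lesion = {0, 7}
        conn = rng.standard_normal((N, N))
        conn = (conn + conn.T) / 2
        np.fill_diagonal(conn, np.nan)
        part = _partition(labels, ("A", "B", "C"), lesion=lesion)
        prof = lc.lesion_profile(conn, part)
        for k in range(K):
            vals = [conn[i, j] for i in lesion for j in range(N)
                    if j not in lesion and labels[j] == k]
            assert prof[k] == pytest.approx(np.mean(vals))

    def test_empty_lesion_set_raises(self):
        part = _partition([0, 0, 1, 1], ("A", "B"))
        with pytest.raises(ValueError):
            lc.lesion_profile(np.zeros((4, 4)), part)


class TestContrastMatrix:
    def _cohort_blocks(self, rng, n_c=20, n_p=6, K=16, shift=None):
        blocks = rng.standard_normal((n_c + n_p, K, K)) * 0.3
        blocks = (blocks + blocks.transpose(0, 2, 1)) / 2
        if shift is not None:
            blocks[n_c:] += shift
        groups = np.array(["control"] * n_c + ["patient"] * n_p)
        sex = np.array(["M", "F"] * ((n_c + n_p) // 2) + ["M"] *
                       ((n_c + n_p) % 2))
        return blocks, groups, sex

    def test_sixteen_networks_have_120_pairwise_cells(self, rng):
        blocks, groups, sex = self._cohort_blocks(rng)
        res = lc.network_contrast_matrix(blocks, groups, sex)
        iu = np.triu_indices(16, 1)
        assert res.p[iu].size == 120
        assert np.isfinite(res.p[iu]).all()

    def test_null_uncorrected_rate_near_alpha(self):
        """Cell-wise tests on exchangeable groups reject at ~5%."""
        rng = np.random.default_rng(11)
        rates = []
        for _ in range(400):
            blocks, groups, sex = self._cohort_blocks(rng, K=4)
            res = lc.network_contrast_matrix(blocks, groups, sex)
            iu = np.triu_indices(4, 1)
            rates.append(np.mean(res.p[iu] < 0.05))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_planted_shift_detected_with_direction(self, rng):
        shift = np.zeros((16, 16))
        shift[2, 3] = shift[3, 2] = -1.5
        blocks, groups, sex = self._cohort_blocks(rng, shift=shift)
        res = lc.network_contrast_matrix(blocks, groups, sex)
        assert res.t[2, 3] < 0
        assert res.mask[2, 3] == 2      # survives Bonferroni over 120

    def test_lesion_row_uses_family_of_K(self, rng):
        blocks, groups, sex = self._cohort_blocks(rng, K=8)
        prof = rng.standard_normal((26, 8)) * 0.3
        prof[20:, 0] -= 2.0
        res = lc.network_contrast_matrix(blocks, groups, sex,
                                         lesion_profiles=prof)
        assert res.lesion_mask[0] == 2
        assert res.lesion_t[0] < 0
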