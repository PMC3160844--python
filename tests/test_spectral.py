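"""Spectral similarity, Laplacians, Fiedler vectors and disk decomposition."""

import math

import numpy as np
import pytest

from spectraldcm import (DCMParams, DistanceMatrix, avoid_large_overlap,
                         build_disk_tree, build_laplacian, decompose_disk,
                         fiedler_vector, gaussian_similarity)
from spectraldcm.spectral import DegenerateDiskError, DiskDecomposition


def _matrix(d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix([f"g{i}" for i in range(d.shape[0])], d)


def _additive_tree_matrix(groups, within, between):
    """Distances for clusters of sizes ``groups``: ``within`` inside a
    cluster, ``between`` across clusters (an additive two-block shape)."""
    n = sum(groups)
    labels = np.repeat(np.arange(len(groups)), groups)
    d = np.full((n, n), float(between))
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                d[i, j] = 0 if i == j else within
    return _matrix(d)


class TestGaussianSimilarity:
    def test_zero_distance_gives_unit_similarity(self):
        m = _matrix([[0, 0, 4], [0, 0, 4], [4, 4, 0]])
        ctx = gaussian_similarity(m, alpha=0.125)
        assert ctx.W[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(ctx.W) == 0)

    def test_monotone_decreasing_in_distance(self):
        m = _matrix([[0, 1, 2, 4], [1, 0, 1, 3], [2, 1, 0, 2], [4, 3, 2, 0]])
        ctx = gaussian_similarity(m, alpha=0.5)
        assert ctx.W[0, 1] > ctx.W[0, 2] > ctx.W[0, 3]

    def test_boundary_value_at_dmax(self):
        m = _matrix([[0, 8], [8, 0]])
        ctx = gaussian_similarity(m, alpha=0.125)
        # w = exp(-d_max^2 / (2 (alpha d_max)^2)) = exp(-1/(2 alpha^2)) = exp(-32)
        assert ctx.W[0, 1] == pytest.approx(math.exp(-32))
        assert ctx.sigma == pytest.approx(1.0)

    def test_degenerate_disk_signalled(self):
        with pytest.raises(DegenerateDiskError):
            gaussian_similarity(_matrix(np.zeros((3, 3))), alpha=0.125)


class TestLaplacians:
    @pytest.fixture
    def ctx(self):
        return gaussian_similarity(
            _additive_tree_matrix([3, 3], within=2, between=10), alpha=0.25)

    @pytest.mark.parametrize("kind", ["unnormalized", "random_walk"])
    def test_rows_sum_to_zero(self, ctx, kind):
        L = build_laplacian(ctx, kind)
        assert np.allclose(L.sum(axis=1), 0, atol=1e-12)

    def test_symmetric_and_random_walk_share_spectrum(self, ctx):
        """If (lam, v) is an eigenpair of L_sym then D^(-1/2) v is an
        eigenvector of L_rw for the same eigenvalue."""
        import scipy.linalg

        Ls = build_laplacian(ctx, "symmetric")
        Lrw = build_laplacian(ctx, "random_walk")
        lam, vecs = scipy.linalg.eigh(Ls)
        for k in range(len(lam)):
            v = vecs[:, k] / np.sqrt(ctx.D)
            assert np.allclose(Lrw @ v, lam[k] * v, atol=1e-8)

    def test_fiedler_orthogonal_to_constant_under_d_inner_product(self, ctx):
        f = fiedler_vector(ctx, "random_walk")
        assert f.eigenvalue >= -1e-12
        assert abs(np.sum(ctx.D * f.vector)) < 1e-8
        assert np.isclose(np.linalg.norm(f.vector), 1.0)

    def test_two_genomes_split_by_sign(self):
        ctx = gaussian_similarity(_matrix([[0, 5], [5, 0]]), alpha=0.125)
        f = fiedler_vector(ctx, "random_walk")
        assert f.vector[0] * f.vector[1] < 0

    def test_two_distant_clusters_split_exactly(self):
        m = _additive_tree_matrix([4, 4], within=2, between=30)
        ctx = gaussian_similarity(m, alpha=0.125)
        f = fiedler_vector(ctx, "random_walk")
        signs = np.sign(f.vector)
        assert set(signs[:4]) != set(signs[4:])
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1


class TestDecomposeDisk:
    def test_large_gap_gives_clean_split(self):
        m = _additive_tree_matrix([4, 4], within=2, between=30)
        d = decompose_disk(range(8), m, DCMParams())
        assert d.overlap == ()
        assert sorted(map(sorted, (d.disk0, d.disk1))) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_bridge_genomes_land_in_overlap(self):
        # two clusters bridged by two middle genomes equidistant to both: the
        # mid genomes get small-magnitude entries and fall in the overlap
        n = 10
        d = np.zeros((n, n))
        # clusters {0..3}, {6..9}; bridge genomes 4, 5
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gi = 0 if i <= 3 else (2 if i >= 6 else 1)
                gj = 0 if j <= 3 else (2 if j >= 6 else 1)
                if gi == gj:
                    d[i, j] = 2
                elif {gi, gj} == {0, 2}:
                    d[i, j] = 16
                else:
                    d[i, j] = 8
        dec = decompose_disk(range(n), _matrix(d), DCMParams())
        assert set(dec.overlap) <= {4, 5}
        ex0, ex1 = set(dec.exclusive0), set(dec.exclusive1)
        assert {0, 1, 2, 3} in (ex0, ex1) or {0, 1, 2, 3} <= (ex0 | ex1)

    def test_invariants_and_determinism(self):
        m = _additive_tree_matrix([3, 5], within=3, between=12)
        p = DCMParams()
        d1 = decompose_disk(range(8), m, p)
        d2 = decompose_disk(range(8), m, p)
        assert d1 == d2
        assert set(d1.disk0) | set(d1.disk1) == set(range(8))
        assert set(d1.disk0) & set(d1.disk1) == set(d1.overlap)

    def test_shrink_invariant_enforced(self):
        with pytest.raises(ValueError):
            DiskDecomposition((0, 1, 2, 3), (0, 1, 2, 3), (2, 3), (2, 3))


class TestAvoidLargeOverlap:
    @staticmethod
    def _two_pairs_and_center(n_center=8, pair_dist=2, long_edge=40):
        """Two tight distant pairs and many center genomes (the shape that
        floods the overlap without the rewrite heuristic)."""
        n = 4 + n_center
        d = np.zeros((n, n))
        def region(k):
            return 0 if k < 2 else (1 if k < 4 else 2)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                ri, rj = region(i), region(j)
                if ri == rj:
                    d[i, j] = pair_dist
                elif {ri, rj} == {0, 1}:
                    d[i, j] = 2 * long_edge
                else:
                    d[i, j] = long_edge
        return _matrix(d)

    def test_rewrites_to_isolate_one_tight_pair(self):
        m = self._two_pairs_and_center()
        dec = decompose_disk(range(12), m, DCMParams())
        assert dec.overlap == ()
        small = min((dec.disk0, dec.disk1), key=len)
        assert set(small) in ({0, 1}, {2, 3})

    def test_empty_overlap_passes_through(self):
        m = _additive_tree_matrix([4, 4], within=2, between=30)
        dec = decompose_disk(range(8), m, DCMParams())
        assert avoid_large_overlap(dec, m, DCMParams()) == dec


class TestBuildDiskTree:
    def test_small_disk_is_single_leaf(self):
        m = _additive_tree_matrix([2, 1], within=2, between=5)
        node = build_disk_tree(m)
        assert node.is_leaf and node.indices == (0, 1, 2)

    def test_four_genomes_split_into_two_pairs(self):
        m = _additive_tree_matrix([2, 2], within=1, between=20)
        node = build_disk_tree(m)
        assert not node.is_leaf
        assert all(len(leaf.indices) == 2 for leaf in node.leaf_disks())

    def test_every_leaf_disk_small_and_nested(self):
        rng = np.random.default_rng(4)
        n = 17
        pts = rng.normal(size=(n, 2)) * 5
        d = np.round(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        node = build_disk_tree(_matrix(d))
        for leaf in node.leaf_disks():
            assert 1 <= len(leaf.indices) <= 3
        def check(nd):
            for ch in nd.children:
                assert set(ch.indices) <= set(nd.indices)
                assert len(ch.indices) < len(nd.indices)
                check(ch)
        check(node)
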