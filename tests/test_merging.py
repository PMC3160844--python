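"""Merging sub-topologies: candidate enumeration, conflicts, gluing, pipeline."""

import numpy as np
import pytest

from spectraldcm import (DCMParams, LabeledTree, conflicting_overlap_edges,
                         evolve_genomes, inversion_distance, fp_fn,
                         merge_nonoverlapping, merge_overlapping, reconstruct,
                         score_topology, topology_count, tree_score,
                         uniform_random_tree)
from spectraldcm.gene_orders import GenomeSet, SignedGeneOrder
from spectraldcm.medians import ScoredTopology
from spectraldcm.merging import (_topology_splits, _base_tree, _enumerate_topologies,
                                 resolve_multifurcations)

from conftest import as_genome


def _scored(tree: LabeledTree) -> ScoredTopology:
    return ScoredTopology(tree, tree_score(tree))


def _evolved_genomes(seed, n=6, g=40, low=1, high=5):
    tree = uniform_random_tree(n, low, high, seed=seed)
    return evolve_genomes(tree, g=g, seed=seed)


def _single(genome):
    t = LabeledTree()
    t.add_vertex(genome)
    return _scored(t)


class TestMergeNonOverlapping:
    def test_two_singletons_give_one_two_leaf_candidate(self):
        a, b = as_genome("a", [1, 2, 3]), as_genome("b", [1, -2, 3])
        best, cands = merge_nonoverlapping(_single(a), _single(b))
        assert cands.n == 1
        assert best.score == inversion_distance(a, b)
        assert len(best.tree.leaves()) == 2

    @staticmethod
    def _two_clusters(seed=5, g=30, spread=2, gap=12):
        """Two 3-genome stars whose closest cross pair is center x center."""
        rng = np.random.default_rng(seed)
        anc = np.arange(1, g + 1, dtype=np.int32)

        def evolve(base, k):
            out = base.copy()
            for _ in range(k):
                L = int(rng.integers(1, g + 1))
                s = int(rng.integers(0, g - L + 1))
                out[s:s + L] = -out[s:s + L][::-1]
            return out

        c0 = anc.copy()
        c1 = evolve(anc, gap)
        mk = lambda nm, arr: SignedGeneOrder(nm, arr)
        t0 = LabeledTree.from_star(
            [mk(f"a{i}", evolve(c0, spread)) for i in range(3)], mk("m0", c0))
        t1 = LabeledTree.from_star(
            [mk(f"b{i}", evolve(c1, spread)) for i in range(3)], mk("m1", c1))
        return _scored(t0), _scored(t1)

    def test_internal_internal_pair_enumerates_exactly_nine(self):
        t0, t1 = self._two_clusters()
        best, cands = merge_nonoverlapping(t0, t1)
        # closest cross pair is the two star centers (internal x internal):
        # 3 incident edges each, hence exactly 9 candidates
        assert cands.n == 9
        assert best.tree.is_binary()
        assert best.tree.leaf_names() == {f"a{i}" for i in range(3)} | {
            f"b{i}" for i in range(3)}

    def test_leaf_internal_pair_enumerates_three(self):
        t0, _ = self._two_clusters()
        # single genome far from everything: closest pair = leaf x internal
        lone = _single(as_genome("z", np.arange(1, 31)))
        best, cands = merge_nonoverlapping(t0, lone)
        assert cands.n == 3

    def test_score_symmetric_under_argument_swap(self):
        t0, t1 = self._two_clusters(seed=9)
        b01, _ = merge_nonoverlapping(t0, t1)
        b10, _ = merge_nonoverlapping(t1, t0)
        assert b01.score == b10.score

    def test_rejects_shared_leaves(self):
        a = as_genome("a", [1, 2])
        with pytest.raises(ValueError, match="disjoint"):
            merge_nonoverlapping(_single(a), _single(a.rename("a")))


class TestConflictingOverlapEdges:
    @staticmethod
    def _quartet_tree(names, split_pairs, genome_map):
        """Binary quartet with the given cherry pairs."""
        t = LabeledTree()
        i1, i2 = t.add_vertex(genome_map["_i1"]), t.add_vertex(genome_map["_i2"])
        t.add_edge(i1, i2)
        for nm, hub in zip(split_pairs[0], (i1, i1)):
            t.add_edge(hub, t.add_vertex(genome_map[nm]))
        for nm, hub in zip(split_pairs[1], (i2, i2)):
            t.add_edge(hub, t.add_vertex(genome_map[nm]))
        return t

    @pytest.fixture
    def genomes(self):
        base = {}
        rng = np.random.default_rng(0)
        for i, nm in enumerate(["A", "B", "C", "D", "_i1", "_i2"]):
            arr = np.arange(1, 9, dtype=np.int32)
            for _ in range(i + 1):
                L = int(rng.integers(1, 9)); s = int(rng.integers(0, 9 - L))
                arr[s:s + L] = -arr[s:s + L][::-1]
            base[nm] = SignedGeneOrder(nm, arr)
        return base

    def test_identical_restrictions_no_conflict(self, genomes):
        t0 = self._quartet_tree("ABCD", (("A", "B"), ("C", "D")), genomes)
        t1 = self._quartet_tree("ABCD", (("A", "B"), ("C", "D")), genomes)
        c0, c1 = conflicting_overlap_edges(t0, t1, {"A", "B", "C", "D"})
        assert not c0 and not c1

    def test_incompatible_quartets_flag_central_edges(self, genomes):
        t0 = self._quartet_tree("ABCD", (("A", "B"), ("C", "D")), genomes)
        t1 = self._quartet_tree("ABCD", (("A", "C"), ("B", "D")), genomes)
        c0, c1 = conflicting_overlap_edges(t0, t1, {"A", "B", "C", "D"})
        assert len(c0) == 1 and len(c1) == 1  # the two central edges

    def test_small_overlap_never_conflicts(self, genomes):
        t0 = self._quartet_tree("ABCD", (("A", "B"), ("C", "D")), genomes)
        t1 = self._quartet_tree("ABCD", (("A", "C"), ("B", "D")), genomes)
        c0, c1 = conflicting_overlap_edges(t0, t1, {"A", "B", "C"})
        assert not c0 and not c1

    def test_empty_overlap_rejected(self, genomes):
        t0 = self._quartet_tree("ABCD", (("A", "B"), ("C", "D")), genomes)
        with pytest.raises(ValueError):
            conflicting_overlap_edges(t0, t0, set())


class TestResolveMultifurcations:
    def test_topology_enumeration_counts(self):
        for k, expected in ((3, 1), (4, 3), (5, 15), (6, 105)):
            assert len(_enumerate_topologies(k)) == expected
            assert len(_enumerate_topologies(k)) == (
                1 if k == 3 else topology_count(k))

    def test_single_degree_four_vertex_gives_three(self):
        a = as_genome("a", [1, 2])
        t = LabeledTree.from_star([a.rename(f"x{i}") for i in range(4)], center=a)
        out, truncated = resolve_multifurcations(t)
        assert len(out) == 3 and not truncated
        assert all(tt.is_binary() for tt in out)

    def test_two_independent_multifurcations_multiply(self):
        a = as_genome("a", [1, 2])
        t = LabeledTree()
        h1 = t.add_vertex(a.rename("h1"))
        h2 = t.add_vertex(a.rename("h2"))
        t.add_edge(h1, h2)
        for i in range(3):
            t.add_edge(h1, t.add_vertex(a.rename(f"l{i}")))
            t.add_edge(h2, t.add_vertex(a.rename(f"r{i}")))
        out, truncated = resolve_multifurcations(t)
        assert len(out) == 9 and not truncated

    def test_binary_tree_passes_through(self):
        a = as_genome("a", [1, 2])
        t = LabeledTree.from_star([a.rename(f"x{i}") for i in range(3)], center=a)
        out, _ = resolve_multifurcations(t)
        assert len(out) == 1

    def test_cap_truncates_but_yields_binary_trees(self):
        a = as_genome("a", [1, 2])
        t = LabeledTree.from_star([a.rename(f"x{i}") for i in range(7)], center=a)
        out, truncated = resolve_multifurcations(t, max_candidates=10)
        assert truncated and len(out) <= 10
        assert all(tt.is_binary() for tt in out)


class TestMergeOverlapping:
    @staticmethod
    def _model_merge_setup(seed=3, n=8, g=40):
        """Model tree split into two leaf subsets sharing an overlap; each
        disk tree is the ground-truth restriction."""
        tree = uniform_random_tree(n, 2, 6, seed=seed)
        gs, model = evolve_genomes(tree, g=g, seed=seed)
        names = sorted(model.tree.leaf_names())
        half = n // 2
        ov = names[half - 1: half + 1]  # two shared genomes
        names0 = names[:half + 1]
        names1 = names[half - 1:]
        t0 = model.tree.restricted_to(names0)
        t1 = model.tree.restricted_to(names1)
        return model, _scored(t0), _scored(t1), ov

    def test_conflict_free_two_genome_overlap_single_candidate(self):
        model, t0, t1, ov = self._model_merge_setup()
        best, cands = merge_overlapping(t0, t1, ov)
        assert cands.n == 1
        assert _topology_splits(best.tree) == _topology_splits(model.tree)

    def test_merged_tree_restricts_back_to_inputs(self):
        model, t0, t1, ov = self._model_merge_setup(seed=12)
        names0 = sorted(t0.tree.leaf_names())
        best, _ = merge_overlapping(t0, t1, ov)
        back = best.tree.restricted_to(names0)
        assert _topology_splits(back) == _topology_splits(t0.tree)

    def test_single_genome_overlap_resolves_multifurcation(self):
        model, t0, t1, _ = self._model_merge_setup(seed=5)
        ov = sorted(t0.tree.leaf_names() & t1.tree.leaf_names())[:1]
        names0 = sorted(t0.tree.leaf_names())
        names1 = set(ov) | (t1.tree.leaf_names() - t0.tree.leaf_names())
        t1b = _scored(model.tree.restricted_to(sorted(names1)))
        t0b = _scored(model.tree.restricted_to(names0))
        best, cands = merge_overlapping(t0b, t1b, ov)
        assert cands.n >= 1
        assert best.tree.leaf_names() == t0b.tree.leaf_names() | t1b.tree.leaf_names()
        assert best.tree.is_binary()

    def test_empty_overlap_rejected(self):
        a, b = as_genome("a", [1, 2]), as_genome("b", [2, 1])
        with pytest.raises(ValueError):
            merge_overlapping(_single(a), _single(b), [])


class TestReconstruct:
    def test_three_genomes_star(self, rng):
        from spectraldcm import inversion_median

        gs = GenomeSet([as_genome("a", [1, 2, 3, 4]), as_genome("b", [1, -3, -2, 4]),
                        as_genome("c", [-2, -1, 3, 4])])
        rec = reconstruct(gs)
        assert rec.score == inversion_median(gs[0], gs[1], gs[2]).score
        assert len(rec.tree.leaves()) == 3

    def test_quartet_with_long_internal_edge(self):
        # one long internal edge: the generating split must be recovered
        rng = np.random.default_rng(2)
        g = 60
        anc = np.arange(1, g + 1, dtype=np.int32)

        def evolve(base, k):
            out = base.copy()
            for _ in range(k):
                L = int(rng.integers(1, g + 1)); s = int(rng.integers(0, g - L + 1))
                out[s:s + L] = -out[s:s + L][::-1]
            return out

        left = anc
        right = evolve(anc, 15)
        gs = GenomeSet([
            SignedGeneOrder("a1", evolve(left, 2)),
            SignedGeneOrder("a2", evolve(left, 2)),
            SignedGeneOrder("b1", evolve(right, 2)),
            SignedGeneOrder("b2", evolve(right, 2)),
        ])
        rec = reconstruct(gs)
        splits = _topology_splits(rec.tree)
        assert frozenset({frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}) in splits

    def test_duplicate_genomes_reattached(self):
        gs_list = [as_genome("a", [1, 2, 3, 4]), as_genome("b", [1, -3, -2, 4]),
                   as_genome("c", [-2, -1, 3, 4]), as_genome("d", [4, 3, 2, 1])]
        gs_list.append(as_genome("a_dup", [1, 2, 3, 4]))
        rec = reconstruct(GenomeSet(gs_list))
        assert rec.tree.leaf_names() == {"a", "b", "c", "d", "a_dup"}
        # the duplicate sits at distance 0 from its twin
        t = rec.tree
        names = {t.label(v).name: v for v in t.leaves()}
        import networkx as nx
        path = nx.shortest_path(t.graph, names["a"], names["a_dup"])
        assert sum(t.length(u, v) for u, v in zip(path, path[1:])) == 0

    def test_score_reported_equals_recomputed(self, np_rng):
        gs, model = _evolved_genomes(seed=21, n=7)
        rec = reconstruct(gs)
        assert rec.score == tree_score(rec.tree)
        assert rec.tree.leaf_names() == {g.name for g in gs}

    def test_easy_regime_recovers_model_tree(self):
        """Well-separated 10-genome tree: every bipartition recovered."""
        tree = uniform_random_tree(10, 2, 4, seed=77)
        gs, model = evolve_genomes(tree, g=100, seed=77)
        rec = reconstruct(gs)
        rep = fp_fn(rec.tree, model.tree)
        assert rep.fp == 0 and rep.fn == 0

    def test_deterministic(self):
        gs, _ = _evolved_genomes(seed=8, n=6)
        from spectraldcm import write_newick

        r1 = reconstruct(gs)
        r2 = reconstruct(gs)
        assert write_newick(r1.tree) == write_newick(r2.tree)
        assert r1.score == r2.score
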