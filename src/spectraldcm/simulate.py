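"""Simulators: model trees and inversion evolution of gene orders.

Three model-tree regimes drive the experiments:

* uniform-random topologies (sequential random leaf addition, which draws
  uniformly from the (2n-5)!! unrooted binary topologies) with integer edge
  lengths sampled uniformly from {0..16};
* pure-birth (birth-death with death rate 0) topologies with the same
  uniform integer edge lengths;
* birth-death topologies whose branch lengths are skewed by a log-uniform
  multiplier 2^s, s ~ U(-2, 2), then uniformly rescaled so the tree diameter
  equals 1x or 2x the gene count, and rounded to integers.

Genomes evolve along a model tree from an ancestral identity permutation of
``g`` genes (100 by default): each edge applies exactly its integer length
in inversions, with inversion lengths drawn uniformly from {1..g} (or from a
rounded, clamped gamma distribution) and the start position uniform among
the placements that fit.  Every internal genome is retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gene_orders import GenomeSet, LabeledTree, SignedGeneOrder

__all__ = [
    "ModelTree",
    "uniform_random_tree",
    "birth_death_tree",
    "assign_uniform_lengths",
    "skew_and_scale",
    "evolve_genomes",
]


@dataclass
class ModelTree:
    """Simulation ground truth: a fully labeled topology with integer
    per-edge inversion counts and the ancestral genome at the root."""

    tree: LabeledTree
    root: int
    ancestor: SignedGeneOrder
    seed: Optional[int] = None

    def leaf_genomes(self) -> GenomeSet:
        leaves = sorted(self.tree.leaves(), key=lambda v: self.tree.label(v).name)
        return GenomeSet([self.tree.label(v) for v in leaves])

    def parsimony_score(self) -> int:
        from .medians import tree_score

        return tree_score(self.tree)


def _leaf_namer(n: int):
    width = max(2, len(str(n - 1)))
    return lambda k: f"G{k:0{width}d}"


def uniform_random_tree(n: int, length_low: int = 0, length_high: int = 16,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None) -> LabeledTree:
    """Uniform unrooted binary topology with integer edge lengths.

    Leaf ``k+1`` attaches to an edge chosen uniformly among the current
    ``2k-3`` edges, which makes every topology equally likely.  Each edge
    length is drawn uniformly from {length_low..length_high}.
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    rng = rng if rng is not None else np.random.default_rng(seed)
    name = _leaf_namer(n)
    t = LabeledTree()
    center = t.add_vertex()
    from .gene_orders import _NamePlaceholder

    for k in range(3):
        t.add_edge(center, t.add_vertex(_NamePlaceholder(name(k))))
    for k in range(3, n):
        edges = sorted(tuple(sorted(e)) for e in t.edges())
        u, v = edges[rng.integers(0, len(edges))]
        x = t.subdivide_edge(u, v)
        t.add_edge(x, t.add_vertex(_NamePlaceholder(name(k))))
    for u, v in t.edges():
        t.set_length(u, v, int(rng.integers(length_low, length_high + 1)))
    return t


def birth_death_tree(n: int, birth: float = 0.001, death: float = 0.0,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> LabeledTree:
    """Pure-birth (Yule) topology with branch lengths in time units.

    Lineages split at rate ``birth`` each until ``n`` tips exist; with
    ``death = 0`` every lineage survives, so the tree is the full birth
    history.  The root (first) split leaves an unrooted binary topology once
    the degree-2 root is suppressed.
    """
    if n < 3:
        raise ValueError("need at least 3 tips")
    if death != 0:
        raise NotImplementedError("only the pure-birth (death=0) regime is supported")
    rng = rng if rng is not None else np.random.default_rng(seed)
    name = _leaf_namer(n)
    t = LabeledTree()
    root = t.add_vertex()
    first = t.add_vertex()
    t.add_edge(root, first, length=0.0)
    active = [first]  # current tips; edge to parent carries elapsed time
    while len(active) < n:
        k = len(active)
        dt = float(rng.exponential(1.0 / (birth * k)))
        for tip in active:
            p = t.neighbors(tip)[0]
            t.set_length(p, tip, t.length(p, tip) + dt)
        i = int(rng.integers(0, k))
        parent = active[i]
        c1, c2 = t.add_vertex(), t.add_vertex()
        t.add_edge(parent, c1, length=0.0)
        t.add_edge(parent, c2, length=0.0)
        active[i] = c1
        active.append(c2)
    from .gene_orders import _NamePlaceholder

    for k, tip in enumerate(sorted(active)):
        t.set_label(tip, _NamePlaceholder(name(k)))
    t.graph.remove_node(root)  # drop the root stem ...
    t.suppress_degree_two()  # ... and the now degree-2 first split
    return t


def assign_uniform_lengths(tree: LabeledTree, length_low: int = 0,
                           length_high: int = 16,
                           rng: Optional[np.random.Generator] = None,
                           seed: Optional[int] = None) -> LabeledTree:
    """Replace all edge lengths with draws from U{length_low..length_high}."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    for u, v in sorted(tuple(sorted(e)) for e in tree.edges()):
        tree.set_length(u, v, int(rng.integers(length_low, length_high + 1)))
    return tree


def skew_and_scale(tree: LabeledTree, diameter_factor: int, g: int = 100,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None) -> LabeledTree:
    """Skew edge lengths by 2^s, s ~ U(-2,2), then rescale to a target diameter.

    After the per-edge multipliers (spanning [1/4, 4]), all lengths are
    scaled by one constant so the maximum leaf-to-leaf path length equals
    ``diameter_factor * g``, and rounded to nearest nonnegative integers.
    The result is a right-skewed integer length distribution: a few long
    edges and many short ones.
    """
    import networkx as nx

    rng = rng if rng is not None else np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in tree.edges())
    for u, v in edges:
        ln = tree.length(u, v)
        if ln is None:
            raise ValueError("skew_and_scale needs provisional edge lengths")
        s = float(rng.uniform(-2.0, 2.0))
        tree.set_length(u, v, float(ln) * (2.0 ** s))
    lg = tree.graph.copy()
    leaves = tree.leaves()
    diam = 0.0
    dist = dict(nx.all_pairs_dijkstra_path_length(lg, weight="length"))
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            diam = max(diam, dist[a][b])
    if diam == 0:
        raise ValueError("zero-diameter tree cannot be scaled")
    scale = (diameter_factor * g) / diam
    for u, v in edges:
        tree.set_length(u, v, int(round(tree.length(u, v) * scale)))
    return tree


def _random_inversion(genes: np.ndarray, g: int, rng: np.random.Generator,
                      length_dist: str, gamma_params) -> None:
    if length_dist == "uniform":
        L = int(rng.integers(1, g + 1))
    elif length_dist == "gamma":
        shape, scale = gamma_params
        L = int(round(rng.gamma(shape, scale)))
        L = min(max(L, 1), g)
    else:
        raise ValueError(f"unknown length distribution {length_dist!r}")
    s = int(rng.integers(0, g - L + 1))
    genes[s : s + L] = -genes[s : s + L][::-1]


def evolve_genomes(tree: LabeledTree, g: int = 100,
                   length_dist: str = "uniform",
                   gamma_params: Optional[tuple[float, float]] = None,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   ) -> tuple[GenomeSet, ModelTree]:
    """Evolve genomes along ``tree`` whose edge lengths are inversion counts.

    The ancestor at the root is the identity permutation of ``g`` genes; a
    pre-order traversal applies exactly ``length`` inversions per edge.
    Returns the leaf genomes and the fully labeled ground-truth model tree
    (internal genomes retained).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    model = tree.copy()
    internal = sorted(v for v in model.vertices() if model.degree(v) >= 2)
    root = internal[0] if internal else sorted(model.vertices())[0]
    ancestor = SignedGeneOrder("ancestor", np.arange(1, g + 1, dtype=np.int32))

    def assign(v: int, parent: Optional[int], genome: SignedGeneOrder) -> None:
        lab = model.label(v)
        if model.is_leaf(v) and lab is not None:
            model.set_label(v, genome.rename(lab.name))
        else:
            model.set_label(v, genome.rename(f"anc{v}"))
        for w in sorted(model.neighbors(v)):
            if w == parent:
                continue
            k = int(model.length(v, w))
            genes = genome.genes.copy()
            for _ in range(k):
                _random_inversion(genes, g, rng, length_dist, gamma_params)
            assign(w, v, SignedGeneOrder("tmp", genes))

    assign(root, None, ancestor)
    mt = ModelTree(tree=model, root=root, ancestor=model.label(root), seed=seed)
    return mt.leaf_genomes(), mt
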