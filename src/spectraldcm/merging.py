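"""Merging sub-topologies of child disks into the parent disk's tree.

Two merge routines mirror the two kinds of disk decomposition:

* **Non-overlapping disks.**  The closest pair of genomes across the two
  trees — internal (reconstructed ancestor) labels included — pins down
  where the trees join.  For the minimizing pair (u, v), every edge incident
  to u is bridged to every edge incident to v by subdividing both edges and
  connecting the two new vertices, giving at most 3 x 3 = 9 candidate
  topologies unless the minimum distance is tied (then the union of
  enumerations over all tied pairs is used).  New vertices are initialized
  with the median of the attached genome and the two already-labeled
  neighbours, every candidate is rescored, and the lowest parsimony score
  wins.

* **Overlapping disks.**  The two trees are compared on the overlap leaves;
  edges whose overlap bipartitions are incompatible with the other tree are
  collapsed (contracted, creating multifurcations).  The trees are then
  glued along the overlap, every multifurcation is expanded into all binary
  resolutions ((2k-5)!! for a degree-k vertex, multiplied across
  multifurcations, capped), and again the best-scoring candidate wins.

``reconstruct`` drives the whole pipeline: pairwise distances, binary disk
tree, base trees for leaf disks of <= 3 genomes, and a post-order sweep of
merges up to the full genome set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .distances import (clear_distance_cache, inversion_distance,
                        pairwise_matrix)
from .gene_orders import GenomeSet, LabeledTree, SignedGeneOrder
from .medians import (ScoredTopology, clear_median_cache, initialize_label,
                      inversion_median, score_topology, tree_score)
from .spectral import DCMParams, DiskNode, build_disk_tree

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "merge_nonoverlapping",
    "conflicting_overlap_edges",
    "merge_overlapping",
    "reconstruct",
]


@dataclass
class CandidateSet:
    """Diagnostics of one merge: every enumerated candidate and its score."""

    trees: list[LabeledTree] = field(default_factory=list)
    scores: list[int] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    truncated: bool = False

    def add(self, tree: LabeledTree, score: int, why: str) -> None:
        self.trees.append(tree)
        self.scores.append(score)
        self.provenance.append(why)

    @property
    def n(self) -> int:
        return len(self.trees)

    def best_index(self) -> int:
        return min(range(self.n), key=lambda i: (self.scores[i], i))


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _union_with(dst: LabeledTree, src: LabeledTree) -> dict[int, int]:
    """Copy ``src`` into ``dst`` (fresh vertex ids); return the id mapping."""
    m: dict[int, int] = {}
    for v in src.vertices():
        m[v] = dst.add_vertex(src.label(v))
    for u, v in src.edges():
        dst.add_edge(m[u], m[v], src.length(u, v))
    return m


def _leaf_by_name(tree: LabeledTree, name: str) -> int:
    for v in tree.leaves():
        lab = tree.label(v)
        if lab is not None and lab.name == name:
            return v
    raise KeyError(f"no leaf named {name!r}")


def _splits_are_incompatible(s1: frozenset, s2: frozenset) -> bool:
    """Two bipartitions of the same ground set are incompatible iff all four
    pairwise side intersections are non-empty."""
    a1, b1 = tuple(s1)
    a2, b2 = tuple(s2)
    return all((a1 & a2, a1 & b2, b1 & a2, b1 & b2))


def _overlap_splits(tree: LabeledTree, overlap: set[str]) -> dict[tuple[int, int], frozenset]:
    """Map each edge whose overlap restriction is a nontrivial bipartition of
    the overlap leaf set to that bipartition."""
    out: dict[tuple[int, int], frozenset] = {}
    for u, v in tree.edges():
        split = tree.edge_split(u, v)
        a, b = tuple(split)
        ra, rb = frozenset(a & overlap), frozenset(b & overlap)
        if len(ra) >= 2 and len(rb) >= 2:
            out[(u, v)] = frozenset({ra, rb})
    return out


def _topology_splits(tree: LabeledTree) -> frozenset:
    """All nontrivial leaf bipartitions of a tree (pure topology)."""
    out = set()
    for u, v in tree.edges():
        s = tree.edge_split(u, v)
        if all(len(side) >= 2 for side in s):
            out.add(s)
    return frozenset(out)


# ---------------------------------------------------------------------------
# non-overlapping merge
# ---------------------------------------------------------------------------


def merge_nonoverlapping(
    t0: ScoredTopology, t1: ScoredTopology, params: Optional[DCMParams] = None
) -> tuple[ScoredTopology, CandidateSet]:
    """Join the trees of two disjoint disks at their closest genome pair."""
    params = params or DCMParams()
    a, b = t0.tree, t1.tree
    if a.n_vertices() == 0 or b.n_vertices() == 0:
        raise ValueError("cannot merge an empty tree")
    if a.leaf_names() & b.leaf_names():
        raise ValueError("non-overlapping merge requires disjoint leaf sets")

    va, vb = sorted(a.vertices()), sorted(b.vertices())
    best_d = None
    tied: list[tuple[int, int]] = []
    for u in va:
        lu = a.label(u)
        for v in vb:
            d = inversion_distance(lu, b.label(v))
            if best_d is None or d < best_d:
                best_d, tied = d, [(u, v)]
            elif d == best_d:
                tied.append((u, v))

    cands = CandidateSet()
    for u, v in tied:
        e0s: list = sorted(tuple(sorted(e)) for e in a.graph.edges(u)) or [None]
        e1s: list = sorted(tuple(sorted(e)) for e in b.graph.edges(v)) or [None]
        for e0 in e0s:
            for e1 in e1s:
                tree = LabeledTree()
                ma = _union_with(tree, a)
                mb = _union_with(tree, b)
                if e0 is None:
                    x0 = ma[u]
                else:
                    p, q = (ma[e0[0]], ma[e0[1]])
                    x0 = tree.subdivide_edge(p, q)
                    tree.set_label(
                        x0,
                        initialize_label(b.label(v), tree.label(p), tree.label(q),
                                         node_budget=params.median_budget),
                    )
                if e1 is None:
                    x1 = mb[v]
                else:
                    p, q = (mb[e1[0]], mb[e1[1]])
                    x1 = tree.subdivide_edge(p, q)
                    tree.set_label(
                        x1,
                        initialize_label(tree.label(x0), tree.label(p), tree.label(q),
                                         node_budget=params.median_budget),
                    )
                tree.add_edge(x0, x1)
                scored = score_topology(tree, max_passes=params.max_passes,
                                        node_budget=params.median_budget)
                cands.add(scored.tree, scored.score, f"pair=({u},{v}) e0={e0} e1={e1}")
    k = cands.best_index()
    if cands.scores.count(cands.scores[k]) > 1:
        logger.info("merge tie: %d equal-score candidates, keeping the first",
                    cands.scores.count(cands.scores[k]))
    best = ScoredTopology(cands.trees[k], cands.scores[k])
    return best, cands


# ---------------------------------------------------------------------------
# overlapping merge
# ---------------------------------------------------------------------------


def conflicting_overlap_edges(
    t0: LabeledTree, t1: LabeledTree, overlap: Iterable[str]
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Edges of each tree whose overlap bipartition is incompatible with some
    overlap bipartition of the other tree.

    Each tree is restricted to the overlap leaves; an internal edge of one
    restricted tree conflicts if its bipartition of the overlap is
    incompatible with some bipartition induced by the other tree.  Returned
    edges are edges of the *original* trees (several original edges can map
    onto one restricted edge; all are reported).
    """
    ov = set(overlap)
    if not ov:
        raise ValueError("empty overlap: use the non-overlapping merge")
    s0 = _overlap_splits(t0, ov)
    s1 = _overlap_splits(t1, ov)
    c0 = {e for e, sp in s0.items()
          if any(_splits_are_incompatible(sp, sq) for sq in s1.values())}
    c1 = {e for e, sp in s1.items()
          if any(_splits_are_incompatible(sp, sq) for sq in s0.values())}
    return c0, c1


def _contract_edges(tree: LabeledTree, edges: Iterable[tuple[int, int]]) -> LabeledTree:
    t = tree.copy()
    alias: dict[int, int] = {}

    def find(x: int) -> int:
        while x in alias:
            x = alias[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        t.contract_edge(ru, rv)
        alias[rv] = ru
    return t


def _core_vertices(tree: LabeledTree, ov: set[str]) -> set[int]:
    """Vertices on paths between overlap leaves (the overlap 'core')."""
    deg = dict(tree.graph.degree())
    alive = set(tree.vertices())
    keep = {v for v in tree.leaves()
            if tree.label(v) is not None and tree.label(v).name in ov}
    changed = True
    while changed:
        changed = False
        for v in list(alive):
            if deg[v] <= 1 and v not in keep:
                alive.discard(v)
                for w in tree.neighbors(v):
                    if w in alive:
                        deg[w] -= 1
                deg[v] = 0
                changed = True
    return alive


def _ov_partition(tree: LabeledTree, core: set[int], v: int, ov: set[str]) -> list[set[str]]:
    """Overlap leaf names grouped by which core branch of ``v`` they sit on."""
    parts = []
    for w in tree.neighbors(v):
        if w not in core:
            continue
        g = tree.graph.copy()
        g.remove_edge(v, w)
        side = nx.node_connected_component(g, w)
        names = {tree.label(x).name for x in side
                 if tree.is_leaf(x) and tree.label(x) is not None
                 and tree.label(x).name in ov}
        parts.append(names)
    return parts


def _meet(tree: LabeledTree, x: int, y: int, z: int) -> int:
    """The unique vertex where the pairwise paths of three vertices meet."""
    pxy = nx.shortest_path(tree.graph, x, y)
    pxz = nx.shortest_path(tree.graph, x, z)
    common = set(pxy) & set(pxz)
    # the meet is the last common vertex along the x->y path
    for v in reversed(pxy):
        if v in common:
            return v
    raise RuntimeError("disconnected tree")  # pragma: no cover


def _glue(base_src: LabeledTree, other: LabeledTree, ov: set[str]) -> LabeledTree:
    """Graft the exclusive structure of ``other`` onto a copy of ``base_src``,
    matching up the shared overlap leaves.  May create multifurcations."""
    base = base_src.copy()

    if len(ov) == 1:
        # the other tree hangs, whole, next to the single shared leaf
        name = next(iter(ov))
        o1 = _leaf_by_name(other, name)
        p1 = other.neighbors(o1)[0]
        o0 = _leaf_by_name(base, name)
        if base.degree(o0) == 0:
            raise ValueError("overlap merge needs the shared leaf attached")
        p0 = base.neighbors(o0)[0]
        m = {}
        for v in other.vertices():
            if v != o1:
                m[v] = base.add_vertex(other.label(v))
        for u, v in other.edges():
            if o1 in (u, v):
                continue
            base.add_edge(m[u], m[v])
        base.add_edge(p0, m[p1])
        return base

    core = _core_vertices(other, ov)
    anchors = {v for v in core
               if other.is_leaf(v) and other.label(v) is not None
               and other.label(v).name in ov}
    ref = min(anchors, key=lambda v: other.label(v).name)

    # DFS over the core from the reference anchor so that chain vertices are
    # inserted in path order
    order = []
    seen = {ref}
    stack = [ref]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in sorted((x for x in other.neighbors(v) if x in core and x not in seen),
                        reverse=True):
            seen.add(w)
            stack.append(w)

    for c in order:
        if c in anchors:
            continue
        hangs = [w for w in other.neighbors(c) if w not in core]
        parts = _ov_partition(other, core, c, ov)
        parts = [p for p in parts if p]
        if not hangs and len(parts) <= 2:
            continue  # plain path vertex with nothing to carry over
        if len(parts) >= 3:
            reps = sorted(min(p) for p in parts)[:3]
            img = _meet(base, *(_leaf_by_name(base, r) for r in reps))
        else:
            img = _insert_on_path(base, other.label(c), parts)
        for w in hangs:
            _graft_subtree(base, other, c, w, img)
    return base


def _insert_on_path(base: LabeledTree, label: SignedGeneOrder,
                    parts: list[set[str]]) -> int:
    """Place a degree-2 core vertex between the two overlap groups it
    separates, positioned by genome distance along the admissible window."""
    A, B = parts
    a = _leaf_by_name(base, min(A))
    b = _leaf_by_name(base, min(B))
    path = nx.shortest_path(base.graph, a, b)
    # admissible window: path edges whose removal puts all of A on one side
    # and all of B on the other
    window = []
    for t in range(len(path) - 1):
        s = base.edge_split(path[t], path[t + 1])
        for side in s:
            if A <= side and not (B & side):
                window.append(t)
                break
    key = inversion_distance(label, base.label(a))
    if window:
        # a key exactly matching an existing internal window vertex means the
        # true position is ambiguous (the vertex, or either adjacent edge);
        # attach at the vertex so multifurcation resolution enumerates all of
        # them (never at a leaf, which must keep degree 1)
        verts = sorted({path[t] for t in window} | {path[t + 1] for t in window},
                       key=path.index)
        for p in verts:
            if (not base.is_leaf(p)
                    and inversion_distance(base.label(p), base.label(a)) == key):
                return p
        pos = window[0]
        for t in window:
            if inversion_distance(base.label(path[t]), base.label(a)) <= key:
                pos = t
        x = base.subdivide_edge(path[pos], path[pos + 1])
        base.set_label(x, label)
        return x
    # no admissible edge (the base tree does not resolve this split): attach
    # at the internal path vertex with the closest genome distance, or on the
    # first path edge when the path has no internal vertex
    inner = [p for p in path if not base.is_leaf(p)]
    if inner:
        return min(inner, key=lambda p: (abs(inversion_distance(base.label(p),
                                                                base.label(a)) - key),
                                         p))
    x = base.subdivide_edge(path[0], path[1])
    base.set_label(x, label)
    return x


def _graft_subtree(base: LabeledTree, other: LabeledTree, c: int, w: int,
                   img: int) -> None:
    """Copy the subtree of ``other`` hanging from c towards w onto ``img``."""
    sub_nodes = _component_without(other, c, w)
    m = {}
    for v in sub_nodes:
        m[v] = base.add_vertex(other.label(v))
    for u, v in other.edges():
        if u in m and v in m:
            base.add_edge(m[u], m[v])
    base.add_edge(img, m[w])


def _component_without(tree: LabeledTree, blocked: int, start: int) -> set[int]:
    g = tree.graph.copy()
    g.remove_node(blocked)
    return set(nx.node_connected_component(g, start))


def _enumerate_topologies(k: int) -> list[nx.Graph]:
    """All unrooted binary topologies whose leaves are 0..k-1 (k >= 3).

    Internal nodes are labeled ('i', t).  Built by sequential edge insertion,
    which enumerates each of the (2k-5)!! topologies exactly once.
    """
    g0 = nx.Graph()
    g0.add_edges_from((("i", 0), x) for x in range(3))
    trees = [g0]
    for leaf in range(3, k):
        nxt = []
        for t in trees:
            for u, v in sorted(t.edges(), key=repr):  # ids mix ints and tuples
                t2 = t.copy()
                t2.remove_edge(u, v)
                mid = ("i", leaf - 2 + 0, len(nxt))  # unique per expansion
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, leaf)
                nxt.append(t2)
        trees = nxt
    return trees


def resolve_multifurcations(tree: LabeledTree, max_candidates: int = 10000
                            ) -> tuple[list[LabeledTree], bool]:
    """Every binary resolution of every multifurcation (capped).

    A degree-k vertex contributes (2k-5)!! local resolutions; independent
    multifurcations multiply.  Returns the candidate list and whether the
    enumeration was truncated at ``max_candidates``.
    """
    work = [tree]
    truncated = False
    while True:
        target = None
        for t in work:
            for v in t.vertices():
                if t.degree(v) >= 4:
                    target = v
                    break
            if target is not None:
                break
        if target is None:
            return work, truncated
        nxt: list[LabeledTree] = []
        for t in work:
            multi = [v for v in t.vertices() if t.degree(v) >= 4]
            if not multi:
                nxt.append(t)
                continue
            v = multi[0]
            ns = sorted(t.neighbors(v))
            for topo in _enumerate_topologies(len(ns)):
                if len(nxt) >= max_candidates:
                    truncated = True
                    break
                t2 = t.copy()
                t2.graph.remove_node(v)
                imap: dict = {}
                for node in topo.nodes:
                    if isinstance(node, tuple):
                        imap[node] = t2.add_vertex(None)
                for x, y in topo.edges():
                    xx = imap[x] if isinstance(x, tuple) else ns[x]
                    yy = imap[y] if isinstance(y, tuple) else ns[y]
                    t2.add_edge(xx, yy)
                nxt.append(t2)
            if truncated:
                break
        work = nxt
        if truncated:
            logger.warning("multifurcation expansion truncated at %d candidates",
                           max_candidates)
            return work, truncated


def _complete_labels(tree: LabeledTree, node_budget: int) -> None:
    """Fill unlabeled vertices from labeled neighbours (median when all three
    neighbour labels are known, copy otherwise); refinement polishes later."""
    while True:
        todo = [v for v in tree.vertices() if tree.label(v) is None]
        if not todo:
            return
        progressed = False
        todo.sort(key=lambda v: -sum(tree.label(w) is not None
                                     for w in tree.neighbors(v)))
        for v in todo:
            labs = [tree.label(w) for w in tree.neighbors(v)
                    if tree.label(w) is not None]
            if not labs:
                continue
            if len(labs) >= 3:
                tree.set_label(v, inversion_median(labs[0], labs[1], labs[2],
                                                   node_budget=node_budget).median)
            else:
                tree.set_label(v, labs[0].rename(f"anc{v}"))
            progressed = True
        if not progressed:  # pragma: no cover - connected tree always progresses
            raise RuntimeError("cannot label tree: no labeled seed")


def merge_overlapping(
    t0: ScoredTopology, t1: ScoredTopology, overlap: Iterable[str],
    params: Optional[DCMParams] = None,
) -> tuple[ScoredTopology, CandidateSet]:
    """Merge two trees that share the ``overlap`` leaf genomes."""
    params = params or DCMParams()
    ov = set(overlap)
    if not ov:
        raise ValueError("empty overlap: use merge_nonoverlapping")
    a, b = t0.tree, t1.tree
    c0, c1 = conflicting_overlap_edges(a, b, ov)
    ac = _contract_edges(a, c0)
    bc = _contract_edges(b, c1)
    glued = _glue(ac, bc, ov)
    raw, truncated = resolve_multifurcations(glued, params.max_candidates)

    cands = CandidateSet(truncated=truncated)
    for i, t in enumerate(raw):
        _complete_labels(t, params.median_budget)
        scored = score_topology(t, max_passes=params.max_passes,
                                node_budget=params.median_budget)
        cands.add(scored.tree, scored.score, f"resolution {i}")
    k = cands.best_index()
    return ScoredTopology(cands.trees[k], cands.scores[k]), cands


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _base_tree(genomes: Sequence[SignedGeneOrder], params: DCMParams) -> ScoredTopology:
    """Direct solution for a leaf disk of 1-3 genomes."""
    if len(genomes) == 1:
        t = LabeledTree()
        t.add_vertex(genomes[0])
        return ScoredTopology(t, 0)
    if len(genomes) == 2:
        t = LabeledTree()
        u = t.add_vertex(genomes[0])
        v = t.add_vertex(genomes[1])
        t.add_edge(u, v)
        return ScoredTopology(t, tree_score(t))
    sol = inversion_median(*genomes, node_budget=params.median_budget)
    t = LabeledTree.from_star(genomes, center=sol.median.rename("anc"))
    return ScoredTopology(t, tree_score(t))


# tied sub-topologies propagated upward so parent merges can re-rank them;
# the cap keeps pathological tie cascades bounded
MAX_TIED_VARIANTS = 4


def _tied_variants(scored: ScoredTopology) -> list[LabeledTree]:
    return [scored.tree, *scored.ties]


def _breakpoint_tree_score(tree: LabeledTree) -> int:
    from .distances import breakpoint_distance

    return sum(breakpoint_distance(tree.label(u), tree.label(v))
               for u, v in tree.edges())


def _pool_best(pool: CandidateSet, params: Optional[DCMParams] = None
               ) -> ScoredTopology:
    """Minimum-score candidate plus distinct equal-score tie topologies.

    Tied finalists get one extra refinement round (equal scores are often
    artifacts of labeling local minima) and are re-ranked by the refined
    score; surviving ties are broken by the total breakpoint-distance score
    of the labeled tree (the classic secondary gene-order criterion), then
    by enumeration order.
    """
    params = params or DCMParams()
    best_score = min(pool.scores)
    tied = [i for i in range(pool.n) if pool.scores[i] == best_score]
    if len(tied) > 1:
        for i in tied:
            rescored = score_topology(pool.trees[i], max_passes=params.max_passes,
                                      node_budget=params.median_budget)
            pool.trees[i] = rescored.tree
            pool.scores[i] = rescored.score
        best_score = min(pool.scores[i] for i in tied)
        tied = [i for i in tied if pool.scores[i] == best_score]
        tied.sort(key=lambda i: (_breakpoint_tree_score(pool.trees[i]), i))
    k = tied[0]
    seen = {frozenset(_topology_splits(pool.trees[k]))}
    ties = []
    for i in tied[1:]:
        sig = frozenset(_topology_splits(pool.trees[i]))
        if sig not in seen and len(ties) < MAX_TIED_VARIANTS - 1:
            seen.add(sig)
            ties.append(pool.trees[i])
    return ScoredTopology(pool.trees[k], best_score, ties=tuple(ties))


def _solve_disk(node: DiskNode, genome_set: GenomeSet,
                params: DCMParams) -> ScoredTopology:
    if node.is_leaf:
        return _base_tree([genome_set[i] for i in node.indices], params)
    s0 = _solve_disk(node.children[0], genome_set, params)
    s1 = _solve_disk(node.children[1], genome_set, params)
    overlap_names = [genome_set[i].name for i in node.decomposition.overlap]
    pool = CandidateSet()
    for a in _tied_variants(s0):
        for b in _tied_variants(s1):
            ta = ScoredTopology(a, s0.score)
            tb = ScoredTopology(b, s1.score)
            if overlap_names:
                _, cands = merge_overlapping(ta, tb, overlap_names, params)
            else:
                _, cands = merge_nonoverlapping(ta, tb, params)
            for t, sc, why in zip(cands.trees, cands.scores, cands.provenance):
                pool.add(t, sc, why)
    return _pool_best(pool, params)


def _nni_variants(tree: LabeledTree, u: int, v: int) -> list[LabeledTree]:
    """The two nearest-neighbour-interchange rearrangements of edge (u, v)."""
    nu = sorted(w for w in tree.neighbors(u) if w != v)
    nv = sorted(w for w in tree.neighbors(v) if w != u)
    if len(nu) != 2 or len(nv) != 2:
        return []
    b = nu[1]
    out = []
    for c in nv:
        t = tree.copy()
        t.graph.remove_edge(u, b)
        t.graph.remove_edge(v, c)
        t.add_edge(u, c)
        t.add_edge(v, b)
        out.append(t)
    return out


def _nni_polish(scored: ScoredTopology, params: DCMParams,
                max_expansions: int = 10) -> ScoredTopology:
    """Hill climb with bounded plateau over NNI moves on internal edges.

    Merge-order candidate selection occasionally settles a nearest-neighbour
    interchange or two away from a strictly better-scoring tree; this search
    accepts strict score improvements immediately and explores a bounded
    number of equal-score neighbours to get past score plateaus.  The final
    equal-score set is ranked by the breakpoint secondary criterion, so the
    parsimony score never increases.
    """

    def expand(tree: LabeledTree):
        internal_edges = sorted(
            (min(u, v), max(u, v)) for u, v in tree.edges()
            if tree.degree(u) == 3 and tree.degree(v) == 3
        )
        for u, v in internal_edges:
            for cand in _nni_variants(tree, u, v):
                yield score_topology(cand, max_passes=params.max_passes,
                                     node_budget=params.median_budget)

    best_score = scored.score
    plateau = [scored.tree, *scored.ties]
    seen = {frozenset(_topology_splits(t)) for t in plateau}
    frontier = list(plateau)
    expansions = 0
    while frontier and expansions < max_expansions:
        tree = frontier.pop(0)
        expansions += 1
        restart = False
        for cand in expand(tree):
            sig = frozenset(_topology_splits(cand.tree))
            if cand.score < best_score:
                best_score = cand.score
                plateau = [cand.tree]
                seen = {sig}
                frontier = [cand.tree]
                restart = True
                break
            if cand.score == best_score and sig not in seen:
                seen.add(sig)
                plateau.append(cand.tree)
                frontier.append(cand.tree)
        if restart:
            continue
    plateau.sort(key=_breakpoint_tree_score)
    return ScoredTopology(plateau[0], best_score, ties=tuple(plateau[1:4]))


def _attach_duplicates(tree: LabeledTree, rep: SignedGeneOrder,
                       dups: Sequence[SignedGeneOrder]) -> None:
    """Re-attach genomes identical to ``rep`` as zero-length cherries."""
    for dup in dups:
        r = _leaf_by_name(tree, rep.name)
        leaf = tree.add_vertex(dup)
        if tree.degree(r) == 0:
            tree.add_edge(r, leaf, length=0)
            continue
        p = tree.neighbors(r)[0]
        y = tree.subdivide_edge(r, p, genome=rep.rename(f"anc_{rep.name}"))
        tree.add_edge(y, leaf, length=0)


def _set_edge_lengths(tree: LabeledTree) -> None:
    for u, v in tree.edges():
        tree.set_length(u, v, inversion_distance(tree.label(u), tree.label(v)))


def reconstruct(genome_set: GenomeSet,
                params: Optional[DCMParams] = None) -> ScoredTopology:
    """Reconstruct a phylogeny for the full genome set.

    Pipeline: deduplicate identical genomes; compute the pairwise inversion
    distance matrix; build the binary disk tree by recursive spectral
    decomposition; solve leaf disks directly; merge post-order.  Edge lengths
    of the returned tree are the inversion distances between endpoint labels,
    and the reported score is recomputed from the final labeling.
    """
    params = params or DCMParams()
    clear_distance_cache()
    clear_median_cache()

    # deduplicate identical gene orders; re-attached at the end
    groups: dict[bytes, list[SignedGeneOrder]] = {}
    for sg in genome_set:
        groups.setdefault(sg.genes.tobytes(), []).append(sg)
    reps = [v[0] for v in groups.values()]

    if len(reps) <= 3:
        scored = _base_tree(reps, params)
    else:
        rep_set = GenomeSet(reps)
        matrix = pairwise_matrix(rep_set, "inversion")
        disk_tree = build_disk_tree(matrix, params)
        scored = _solve_disk(disk_tree, rep_set, params)
        scored = _nni_polish(scored, params)

    tree = scored.tree
    for key, members in groups.items():
        if len(members) > 1:
            _attach_duplicates(tree, members[0], members[1:])
    _set_edge_lengths(tree)
    return ScoredTopology(tree, tree_score(tree), scored.passes, ties=scored.ties)
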