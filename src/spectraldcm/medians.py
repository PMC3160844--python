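"""Inversion medians and iterative parsimony scoring of a fixed topology.

The median problem — find a genome minimizing the summed inversion distance
to three given genomes — is NP-hard; it is the engine of gene-order maximum
parsimony.  The solver here is an exact branch-and-bound over inversion
sequences, started from the input genome with the smallest summed distance
to the other two and pruned with the metric half-perimeter bound

    score(m) >= depth(v) + ceil((d(v,B) + d(v,C) + d(B,C)) / 2)

valid for every genome in the shortest-path subtree below a search node
``v``.  A steepest-descent pass seeds the incumbent, so easy (near-additive)
instances are proven optimal without expanding a single node.  A node budget
caps the search on hard instances, in which case the best genome found so
far is returned flagged as heuristic.

Scoring a fixed topology follows the classic gene-order parsimony loop:
sweep the internal vertices, replace each label by the median of its three
neighbours whenever that strictly lowers the tree score, and repeat until a
full pass makes no change.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import scan_all_neighbors
from .distances import inversion_distance
from .gene_orders import LabeledTree, SignedGeneOrder

__all__ = [
    "MedianSolution",
    "ScoredTopology",
    "inversion_median",
    "score_topology",
    "initialize_label",
    "tree_score",
    "clear_median_cache",
]

DEFAULT_NODE_BUDGET = 2000
DEFAULT_MAX_PASSES = 50

_median_cache: dict[tuple, "MedianSolution"] = {}


def clear_median_cache() -> None:
    _median_cache.clear()


@dataclass(frozen=True)
class MedianSolution:
    """An inversion median and its score; ``exact`` is False when the node
    budget was exhausted and the best-so-far genome was returned."""

    median: SignedGeneOrder
    score: int
    exact: bool = True


def _half_perimeter(dab: int, dac: int, dbc: int) -> int:
    return (dab + dac + dbc + 1) // 2


class _Budget:
    __slots__ = ("left",)

    def __init__(self, n: int) -> None:
        self.left = n


def inversion_median(
    a: SignedGeneOrder,
    b: SignedGeneOrder,
    c: SignedGeneOrder,
    upper_bound: Optional[int] = None,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> MedianSolution:
    """A genome minimizing d(m,a) + d(m,b) + d(m,c) under inversion distance.

    Exact unless the branch-and-bound exceeds ``node_budget`` expansions, in
    which case the incumbent is returned with ``exact=False``.  The
    ``upper_bound`` argument, when given, additionally prunes branches that
    cannot beat it (useful when the caller already holds a labeling of that
    score and only cares about strict improvements); the returned score may
    then exceed ``upper_bound``.
    """
    key = (
        tuple(sorted((a.genes.tobytes(), b.genes.tobytes(), c.genes.tobytes()))),
        upper_bound,
    )
    cached = _median_cache.get(key)
    if cached is not None:
        return cached

    dab = inversion_distance(a, b)
    dac = inversion_distance(a, c)
    dbc = inversion_distance(b, c)
    lb = _half_perimeter(dab, dac, dbc)

    # incumbent from the three inputs; start genome = smallest distance sum
    sums = [dab + dac, dab + dbc, dac + dbc]
    order = sorted(range(3), key=lambda k: (sums[k], k))
    genomes = (a, b, c)
    start = genomes[order[0]]
    best_genome, best_score = start, sums[order[0]]

    if best_score > lb:
        # multi-start plateau descent: all three inputs seed the incumbent
        for k in order:
            g, s = _steepest_descent(genomes[k], genomes, sums[k], lb)
            if s < best_score:
                best_genome, best_score = g, s
            if best_score <= lb:
                break

    if best_score - lb >= 2:
        # geodesic stage for hard (distant) triples: walk a shortest reversal
        # path between the two non-start inputs, tracking the point closest
        # to the start genome; on near-additive data the median sits on or
        # near that path, far beyond the reach of local descent
        o1, o2 = genomes[order[1]], genomes[order[2]]
        g, s = _geodesic_candidate(o1, o2, start, genomes)
        if s < best_score:
            best_genome, best_score = g, s
        if best_score > lb:
            g2, s2 = _steepest_descent(g, genomes, s, lb)
            if s2 < best_score:
                best_genome, best_score = g2, s2

    exact = True
    if best_score > lb:
        # the B&B proves optimality when the incumbent sits close to the
        # half-perimeter bound; with a large residual slack the proof is out
        # of reach and a token budget only polishes the incumbent
        if best_score - lb > 3:
            node_budget = min(node_budget, node_budget // 10 + 1)
        budget = _Budget(node_budget)
        others = [genomes[order[1]], genomes[order[2]]]
        d_oth = dbc if order[0] == 0 else (dac if order[0] == 1 else dab)
        cap = best_score if upper_bound is None else min(best_score, upper_bound + 1)
        best_genome, best_score, exact = _branch_and_bound(
            start, others[0], others[1], d_oth, best_genome, best_score, lb, budget, cap
        )

    sol = MedianSolution(best_genome.rename("median"), int(best_score), exact)
    if len(_median_cache) > 200_000:
        _median_cache.clear()
    _median_cache[key] = sol
    return sol


def _steepest_descent(start, targets, start_score, lb, max_plateau=24):
    """Greedy incumbent: best strictly-improving inversion, with a bounded
    number of equal-score sideways steps to slip out of shallow minima."""
    cur = start.genes
    cur_score = start_score
    best, best_score = cur, cur_score
    ta, tb, tc = (t.genes for t in targets)
    seen = {cur.tobytes()}
    plateau = 0
    while best_score > lb:
        da, db, dc = scan_all_neighbors(cur, ta, tb, tc)
        tot = da.astype(np.int64) + db + dc
        k = int(np.argmin(tot))  # argmin takes the first = lexicographic min
        if int(tot[k]) < cur_score:
            cur = _neighbor(cur, k)
            cur_score = int(tot[k])
            seen.add(cur.tobytes())
            plateau = 0
            if cur_score < best_score:
                best, best_score = cur, cur_score
            continue
        if int(tot[k]) > cur_score or plateau >= max_plateau:
            break
        stepped = False
        for k in np.nonzero(tot == cur_score)[0]:
            child = _neighbor(cur, int(k))
            key = child.tobytes()
            if key not in seen:
                cur = child
                seen.add(key)
                plateau += 1
                stepped = True
                break
        if not stepped:
            break
    return SignedGeneOrder("median", best), best_score


def _geodesic_candidate(src, dst, third, targets):
    """Best genome on a greedy shortest reversal path from ``src`` to ``dst``.

    Each step applies a reversal that reduces the distance to ``dst`` by one,
    choosing among them the one closest to ``third`` (ties lexicographic).
    Along the path d(m, src) + d(m, dst) stays equal to d(src, dst), so the
    summed median score is minimized where the path passes nearest ``third``.
    """
    cur = src.genes
    d_dst = int(inversion_distance(src, dst))
    best, best_third = cur, int(inversion_distance(src, third))
    while d_dst > 0:
        da, db, dc = scan_all_neighbors(cur, dst.genes, third.genes, third.genes)
        closer = np.nonzero(da == d_dst - 1)[0]
        if closer.size == 0:  # pragma: no cover - HP theory guarantees a move
            break
        k = int(closer[np.argmin(db[closer])])
        cur = _neighbor(cur, k)
        d_dst -= 1
        if int(db[k]) < best_third:
            best, best_third = cur, int(db[k])
    genome = SignedGeneOrder("median", best)
    score = sum(int(inversion_distance(genome, t)) for t in targets)
    return genome, score


def _neighbor(genes: np.ndarray, flat_index: int) -> np.ndarray:
    """Materialize neighbor ``flat_index`` of the lexicographic (i, j) scan."""
    g = genes.size
    t = flat_index
    for i in range(g):
        row = g - i
        if t < row:
            j = i + t
            break
        t -= row
    out = genes.copy()
    out[i : j + 1] = -out[i : j + 1][::-1]
    return out


def _branch_and_bound(start, tb, tc, dbc, best_genome, best_score, lb, budget, cap):
    """DFS over inversion sequences from ``start`` along shortest paths.

    Children are expanded best-bound-first (ties by lexicographic inversion
    order); a child at depth t+1 survives only if it lies at distance t+1
    from the start and its half-perimeter bound beats the pruning cutoff
    (the incumbent score, or the caller-provided cap when tighter).
    """
    exact = True
    a_genes = start.genes

    def cutoff() -> int:
        return min(best_score, cap)

    def dfs(q: np.ndarray, depth: int) -> None:
        nonlocal best_genome, best_score, exact
        if budget.left <= 0:
            exact = False
            return
        budget.left -= 1
        da, db, dc = scan_all_neighbors(q, a_genes, tb.genes, tc.genes)
        on_shell = da == depth + 1
        bound = (depth + 1) + (db.astype(np.int64) + dc + dbc + 1) // 2
        score = (depth + 1) + db.astype(np.int64) + dc
        live = np.nonzero(on_shell & (bound < cutoff()))[0]
        for k in live[np.argsort(bound[live], kind="stable")]:
            if cutoff() <= lb:
                return
            if int(bound[k]) >= cutoff():
                continue
            child = _neighbor(q, int(k))
            if int(score[k]) < best_score:
                best_genome = SignedGeneOrder("median", child)
                best_score = int(score[k])
                if best_score <= lb:
                    return
            if int(bound[k]) < cutoff():
                dfs(child, depth + 1)
            if budget.left <= 0:
                exact = False
                return

    dfs(a_genes, 0)
    return best_genome, best_score, exact or best_score <= lb


def initialize_label(
    attached: SignedGeneOrder, n1: SignedGeneOrder, n2: SignedGeneOrder,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> SignedGeneOrder:
    """Initial genome for a new internal vertex: the median of the genome
    being attached and the two already-labeled neighbor genomes."""
    for sg in (attached, n1, n2):
        if sg is None:
            raise ValueError("initialize_label requires all three neighbor labels")
    return inversion_median(attached, n1, n2, node_budget=node_budget).median


@dataclass
class ScoredTopology:
    """A fully labeled tree with its parsimony score.

    ``ties`` holds alternative trees of the same score (distinct topologies)
    when the producing search ended in a tie; the primary ``tree`` is always
    the deterministic first choice.
    """

    tree: LabeledTree
    score: int
    passes: int = 0
    ties: tuple = ()

    def recomputed_score(self) -> int:
        return tree_score(self.tree)


def tree_score(tree: LabeledTree) -> int:
    """Parsimony score: sum of inversion distances across all edges."""
    total = 0
    for u, v in tree.edges():
        lu, lv = tree.label(u), tree.label(v)
        if lu is None or lv is None:
            raise ValueError("tree_score requires a fully labeled tree")
        total += inversion_distance(lu, lv)
    return total


def _visit_order(tree: LabeledTree) -> list[int]:
    """Internal vertices in BFS order from the lowest-id leaf (fixed)."""
    leaves = sorted(tree.leaves())
    if not leaves:
        return []
    order, seen = [], {leaves[0]}
    queue = deque([leaves[0]])
    while queue:
        v = queue.popleft()
        if tree.degree(v) >= 2:
            order.append(v)
        for w in sorted(tree.neighbors(v)):
            if w not in seen:
                seen.add(w)
                queue.append(w)
    return order


def score_topology(
    tree: LabeledTree,
    max_passes: int = DEFAULT_MAX_PASSES,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> ScoredTopology:
    """Iteratively refine internal labels by local medians until convergence.

    Each internal vertex label is replaced by the inversion median of its
    three neighbours whenever that strictly lowers the tree score; passes
    repeat until one makes no change or ``max_passes`` is reached.  When the
    vertex-wise descent converges, joint two-vertex moves across internal
    edges (median proposals that bypass the partner vertex) are tried, since
    adjacent labels can be locked in a mutual local minimum that no single
    relabeling escapes.  The score never increases across passes.  The input
    tree is modified in place.
    """
    tree.validate()
    internal = tree.internal_vertices()
    for v in internal:
        if tree.degree(v) != 3:
            raise ValueError("score_topology requires a binary tree")
        if tree.label(v) is None:
            raise ValueError("score_topology requires initial internal labels")

    order = _visit_order(tree)
    passes = 0
    # plateau moves (equal-score relabelings) help escape local minima of the
    # coordinate descent; capped to guarantee termination
    plateau_left = 3 * max(1, len(order))
    while passes < max_passes:
        passes += 1
        improved = False
        for v in order:
            nbrs = [tree.label(w) for w in tree.neighbors(v)]
            cur = tree.label(v)
            local = sum(inversion_distance(cur, x) for x in nbrs)
            if local == 0:
                continue
            lb = _half_perimeter(
                inversion_distance(nbrs[0], nbrs[1]),
                inversion_distance(nbrs[0], nbrs[2]),
                inversion_distance(nbrs[1], nbrs[2]),
            )
            if local <= lb:
                continue  # provably optimal already
            sol = inversion_median(nbrs[0], nbrs[1], nbrs[2], node_budget=node_budget)
            if sol.score < local:
                tree.set_label(v, sol.median.rename(f"anc{v}"))
                improved = True
            elif (sol.score == local and plateau_left > 0
                  and sol.median != cur):
                tree.set_label(v, sol.median.rename(f"anc{v}"))
                plateau_left -= 1
                improved = True  # a changed label can unlock later improvements
        if not improved:
            if not _edge_refine_pass(tree, node_budget):
                break
    return ScoredTopology(tree, tree_score(tree), passes)


def _edge_refine_pass(tree: LabeledTree, node_budget: int) -> bool:
    """One sweep of joint two-vertex relabelings across internal edges.

    For adjacent internal vertices u, v with outer neighbours (a, b) and
    (c, d), candidate labels for u are seeded from medians that skip v
    (median(a, b, c) and median(a, b, d)), v is re-solved against the
    candidate, and the pair is accepted when the five affected edges get
    strictly cheaper.  Returns whether anything changed.
    """
    changed = False
    for u, v in sorted((min(a, b), max(a, b)) for a, b in tree.edges()):
        if tree.is_leaf(u) or tree.is_leaf(v):
            continue
        nu = [w for w in tree.neighbors(u) if w != v]
        nv = [w for w in tree.neighbors(v) if w != u]
        a, b = (tree.label(w) for w in nu)
        c, d = (tree.label(w) for w in nv)
        xu, xv = tree.label(u), tree.label(v)

        def cost(x, y):
            return (inversion_distance(a, x) + inversion_distance(b, x)
                    + inversion_distance(x, y)
                    + inversion_distance(y, c) + inversion_distance(y, d))

        best = (cost(xu, xv), xu, xv)
        seeds = {xu,
                 inversion_median(a, b, c, node_budget=node_budget).median,
                 inversion_median(a, b, d, node_budget=node_budget).median}
        for x in sorted(seeds, key=lambda s: s.genes.tobytes()):
            y = inversion_median(c, d, x, node_budget=node_budget).median
            x2 = inversion_median(a, b, y, node_budget=node_budget).median
            for xx, yy in ((x, y), (x2, y)):
                cc = cost(xx, yy)
                if cc < best[0]:
                    best = (cc, xx, yy)
        if best[1] is not xu or best[2] is not xv:
            if best[0] < cost(xu, xv):
                tree.set_label(u, best[1].rename(f"anc{u}"))
                tree.set_label(v, best[2].rename(f"anc{v}"))
                changed = True
    return changed
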