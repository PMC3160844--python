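"""Topological accuracy against model trees and decomposition quality.

Accuracy is counted on internal edges only: FP is the number of internal
bipartitions of the reconstruction absent from the model tree, FN the number
of model bipartitions absent from the reconstruction; (FP+FN)/2 is half the
Robinson-Foulds distance for fully binary pairs.  Edges shorter than 0.5 are
treated as zero-length and contracted before comparison, so integer-length
model trees lose exactly their length-0 edges.

A disk decomposition is *compatible* when some model-tree edge separates the
exclusive region of one disk from the exclusive region of the other (overlap
genomes do not matter).  An incompatible decomposition is still
*recoverable* when merging the correct sub-topologies of the two disks can
reproduce the correct topology; this is probed by literally replaying the
merge on the model tree's induced subtrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .gene_orders import LabeledTree
from .medians import ScoredTopology
from .merging import (_topology_splits, merge_nonoverlapping,
                      merge_overlapping)
from .simulate import ModelTree
from .spectral import DCMParams, DiskDecomposition

__all__ = [
    "AccuracyReport",
    "internal_bipartitions",
    "fp_fn",
    "classify_decomposition",
    "replay_merge",
]


@dataclass(frozen=True)
class AccuracyReport:
    fp: int
    fn: int
    n_internal_model: int

    @property
    def rf_half(self) -> float:
        return (self.fp + self.fn) / 2


def _contract_short_edges(tree: LabeledTree, threshold: float) -> LabeledTree:
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for u, v in list(t.edges()):
            ln = t.length(u, v)
            # only internal edges collapse; external (pendant) edges carry no
            # bipartition and must keep their leaf either way
            if ln is not None and ln < threshold and not t.is_leaf(u) and not t.is_leaf(v):
                t.contract_edge(u, v)
                changed = True
                break
    return t


def internal_bipartitions(tree: LabeledTree, length_threshold: float = 0.5
                          ) -> set[frozenset]:
    """Leaf-name bipartitions of the internal edges, after contracting edges
    shorter than ``length_threshold`` (edges without lengths are kept)."""
    if len(tree.leaves()) < 4:
        return set()
    t = _contract_short_edges(tree, length_threshold)
    return set(_topology_splits(t))


def fp_fn(reconstructed: LabeledTree, model: LabeledTree,
          length_threshold: float = 0.5) -> AccuracyReport:
    """False-positive / false-negative internal edge counts.

    External edges never contribute; both trees are collapsed at the length
    threshold first.  Leaf name sets must agree.
    """
    ln_r, ln_m = reconstructed.leaf_names(), model.leaf_names()
    if ln_r != ln_m:
        raise ValueError(
            f"leaf sets differ: only in reconstruction {sorted(ln_r - ln_m)[:5]}, "
            f"only in model {sorted(ln_m - ln_r)[:5]}"
        )
    sr = internal_bipartitions(reconstructed, length_threshold)
    sm = internal_bipartitions(model, length_threshold)
    return AccuracyReport(fp=len(sr - sm), fn=len(sm - sr),
                         n_internal_model=len(sm))


def _steiner_vertices(tree: LabeledTree, names: set[str]) -> set[int]:
    """Vertices of the minimal subtree spanning the named leaves."""
    keep = {v for v in tree.leaves()
            if tree.label(v) is not None and tree.label(v).name in names}
    if not keep:
        raise ValueError(f"unknown genomes: {sorted(names)[:5]}")
    alive = set(tree.vertices())
    deg = dict(tree.graph.degree())
    changed = True
    while changed:
        changed = False
        for v in list(alive):
            if deg[v] <= 1 and v not in keep:
                alive.discard(v)
                for w in tree.neighbors(v):
                    if w in alive:
                        deg[w] -= 1
                changed = True
    return alive


def classify_decomposition(decomp: DiskDecomposition, model: ModelTree,
                           names: Optional[list[str]] = None) -> str:
    """``"compatible"`` iff some model-tree edge separates the two exclusive
    regions; genomes in the overlap do not affect the outcome.

    ``names`` maps decomposition indices to genome names (defaults to the
    model tree's sorted leaf names, matching the simulators' index order).
    """
    if names is None:
        names = sorted(model.tree.leaf_names())
    excl0 = {names[i] for i in decomp.exclusive0}
    excl1 = {names[i] for i in decomp.exclusive1}
    model_names = model.tree.leaf_names()
    unknown = (excl0 | excl1) - model_names
    if unknown:
        raise ValueError(f"genomes not in model tree: {sorted(unknown)[:5]}")
    s0 = _steiner_vertices(model.tree, excl0)
    s1 = _steiner_vertices(model.tree, excl1)
    # an edge separating the regions exists iff their spanning subtrees are
    # vertex-disjoint
    return "compatible" if not (s0 & s1) else "incompatible"


def replay_merge(decomp: DiskDecomposition, model: ModelTree,
                 names: Optional[list[str]] = None,
                 params: Optional[DCMParams] = None) -> str:
    """Probe recoverability of a decomposition by replaying the merge.

    The correct sub-topology of each disk (the model tree restricted to the
    disk's genomes, ground-truth internal genomes retained) is fed to the
    merge; the decomposition is *recoverable* when the enumerated candidate
    set contains the model topology, i.e. the decomposition does not exclude
    the true tree from the search space.  Compatible decompositions are
    vacuously recoverable.
    """
    params = params or DCMParams()
    if classify_decomposition(decomp, model, names) == "compatible":
        return "recoverable"
    if names is None:
        names = sorted(model.tree.leaf_names())
    names0 = [names[i] for i in decomp.disk0]
    names1 = [names[i] for i in decomp.disk1]
    overlap = [names[i] for i in decomp.overlap]

    def restricted(subset: list[str]) -> ScoredTopology:
        from .medians import tree_score

        t = model.tree.restricted_to(subset)
        return ScoredTopology(t, tree_score(t))

    t0, t1 = restricted(names0), restricted(names1)
    if overlap:
        _, cands = merge_overlapping(t0, t1, overlap, params)
    else:
        _, cands = merge_nonoverlapping(t0, t1, params)

    target = _topology_splits(model.tree.restricted_to(sorted(set(names0 + names1))))
    for t in cands.trees:
        if _topology_splits(t) == target:
            return "recoverable"
    return "irrecoverable"
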