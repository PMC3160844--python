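"""Rearrangement distances between signed gene orders.

The primary metric is the inversion (reversal) distance of Hannenhalli and
Pevzner: the minimum number of inversions transforming one signed
permutation into the other, computed from the breakpoint graph as
``breakpoints - cycles + hurdles + fortress``.  A breakpoint distance is
provided as a cheaper alternative, and full pairwise matrices feed the
spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .gene_orders import GenomeSet, SignedGeneOrder

__all__ = [
    "inversion_distance",
    "breakpoint_distance",
    "pairwise_matrix",
    "topology_count",
    "DistanceMatrix",
    "write_phylip",
    "clear_distance_cache",
]

# distance calls repeat heavily while scoring trees; memoize on genome bytes
_dist_cache: dict[tuple[bytes, bytes], int] = {}


def clear_distance_cache() -> None:
    _dist_cache.clear()


def _check_pair(a: SignedGeneOrder, b: SignedGeneOrder) -> None:
    if a.g != b.g:
        raise ValueError(
            f"mismatched gene sets: {a.name} has g={a.g}, {b.name} has g={b.g}"
        )


def inversion_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Minimum number of inversions transforming ``a`` into ``b``.

    Symmetric, zero iff the signed sequences are equal, and a metric on
    signed permutations of the shared gene set.
    """
    _check_pair(a, b)
    ka, kb = a.genes.tobytes(), b.genes.tobytes()
    key = (ka, kb) if ka <= kb else (kb, ka)
    hit = _dist_cache.get(key)
    if hit is not None:
        return hit
    d = int(_kernels.rev_dist_pair(a.genes, b.genes))
    if len(_dist_cache) > 2_000_000:  # safety valve, never hit at desk scale
        _dist_cache.clear()
    _dist_cache[key] = d
    return d


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of signed adjacencies of ``a`` absent from ``b``.

    Both terminal adjacencies against the frame markers ``0`` and ``g+1``
    are included; adjacency (x, y) is identified with (-y, -x).
    """
    _check_pair(a, b)
    g = a.g

    def adjacencies(sg: SignedGeneOrder) -> set[tuple[int, int]]:
        seq = [0] + [int(x) for x in sg.genes] + [g + 1]
        out = set()
        for x, y in zip(seq, seq[1:]):
            out.add((x, y) if (x, y) <= (-y, -x) else (-y, -x))
        return out

    return len(adjacencies(a) - adjacencies(b))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances among named genomes."""

    names: list[str]
    d: np.ndarray
    metric: str = "inversion"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match name count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.names)

    def submatrix(self, indices: Sequence[int]) -> "DistanceMatrix":
        idx = list(indices)
        return DistanceMatrix(
            [self.names[i] for i in idx], self.d[np.ix_(idx, idx)], self.metric
        )

    def __getitem__(self, ij: tuple[int, int]):
        return self.d[ij]


_METRICS: dict[str, Callable[[SignedGeneOrder, SignedGeneOrder], int]] = {
    "inversion": inversion_distance,
    "breakpoint": breakpoint_distance,
}


def pairwise_matrix(genome_set: GenomeSet, metric: str = "inversion") -> DistanceMatrix:
    """All pairwise distances among the genomes of ``genome_set``."""
    if genome_set.n < 2:
        raise ValueError("need at least 2 genomes for a distance matrix")
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    n = genome_set.n
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(genome_set[i], genome_set[j])
    return DistanceMatrix(genome_set.names, d, metric)


def correct_distances(matrix: DistanceMatrix, method: Optional[str] = None) -> DistanceMatrix:
    """Hook for saturation corrections of estimated distances.

    Only the identity correction is implemented; the hook exists so that
    corrected metrics can be slotted in without touching callers.
    """
    if method not in (None, "none"):
        raise NotImplementedError(f"distance correction {method!r} not available")
    return matrix


def topology_count(n: int) -> int:
    """Number of distinct unrooted binary topologies on ``n`` labeled leaves.

    Equals the double factorial (2n-5)!!, e.g. 15 for five leaves and
    2,027,025 for ten.
    """
    if n < 3:
        raise ValueError("unrooted binary topologies need n >= 3 leaves")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def write_phylip(matrix: DistanceMatrix, dest) -> None:
    """Write a PHYLIP square distance matrix (for distance-method tools)."""
    if isinstance(dest, str):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_phylip(matrix, fh)
        return
    dest.write(f"{matrix.n}\n")
    for i, name in enumerate(matrix.names):
        row = " ".join(f"{float(x):g}" for x in matrix.d[i])
        dest.write(f"{name[:10]:<10s} {row}\n")
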