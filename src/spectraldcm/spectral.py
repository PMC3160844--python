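"""Spectral disk decomposition of a genome set.

Every edge of a phylogenetic tree bipartitions its leaves, and genome sets
separated by a long uninterrupted edge are highly dissimilar; spectral graph
bipartitioning detects exactly that signal.  The decomposition works on a
Gaussian similarity graph over the pairwise distances,

    w_ij = exp(-d_ij^2 / (2 sigma^2)),    sigma = alpha * d_max,

takes the Fiedler vector (eigenvector of the second-smallest eigenvalue) of
the random-walk Laplacian ``D^-1 (D - W)``, splits genomes by the sign of
their entry, and uses entry magnitudes as confidence: when the gap across
zero is small, low-magnitude genomes near the boundary are placed in an
overlapping region shared by both disks.  The random-walk (or symmetric)
normalization is preferred over the unnormalized Laplacian because boundary
genomes should get small magnitudes regardless of how many close neighbours
they have.

Recursive application down to disks of at most three genomes yields the
binary disk tree that drives the divide-and-conquer reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .distances import DistanceMatrix

__all__ = [
    "DCMParams",
    "SpectralContext",
    "FiedlerResult",
    "DiskDecomposition",
    "DiskNode",
    "DegenerateDiskError",
    "gaussian_similarity",
    "build_laplacian",
    "fiedler_vector",
    "decompose_disk",
    "avoid_large_overlap",
    "build_disk_tree",
]


class DegenerateDiskError(ValueError):
    """All genomes in the disk are at pairwise distance zero."""


@dataclass(frozen=True)
class DCMParams:
    """Tunable knobs of the disk-covering method.

    alpha
        Gaussian bandwidth as a fraction of the maximum pairwise distance
        within the disk being decomposed (sigma = alpha * d_max).
    theta1
        Gap threshold that triggers an overlapping decomposition; applied
        as theta1 / sqrt(n) for a disk of n genomes (eigenvectors are
        unit-normalized, so entry scales shrink with n).
    theta2
        Consecutive-entry gap at which the outward walk from the partition
        boundary stops; applied as theta2 / sqrt(n).
    max_overlap_fraction
        Hard cap on |overlap| / |disk|.
    laplacian_kind
        "random_walk" (default), "symmetric", or "unnormalized".
    median_budget, max_candidates, max_passes
        Downstream search budgets threaded through the pipeline.
    """

    alpha: float = 0.125
    theta1: float = 0.5
    theta2: float = 0.25
    max_overlap_fraction: float = 0.5
    laplacian_kind: str = "random_walk"
    median_budget: int = 2000
    max_candidates: int = 10000
    max_passes: int = 50

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.theta2 <= self.theta1):
            raise ValueError("need 0 < theta2 <= theta1")
        if not (0 <= self.max_overlap_fraction <= 1):
            raise ValueError("max_overlap_fraction must be in [0, 1]")
        if self.laplacian_kind not in ("unnormalized", "symmetric", "random_walk"):
            raise ValueError(f"unknown laplacian kind {self.laplacian_kind!r}")


@dataclass
class SpectralContext:
    """Similarity matrix and degrees for one disk."""

    W: np.ndarray
    D: np.ndarray  # diagonal degree values (row sums of W)
    sigma: float
    d_max: float


@dataclass
class FiedlerResult:
    eigenvalue: float
    vector: np.ndarray  # unit Euclidean norm, deterministic sign


@dataclass(frozen=True)
class DiskDecomposition:
    """One overlapping bipartition of a genome index set.

    ``disk0`` and ``disk1`` both include the overlap; the exclusive regions
    ``disk0 - overlap`` and ``disk1 - overlap`` are non-empty and both disks
    are strictly smaller than the parent (termination guarantee).
    """

    parent: tuple[int, ...]
    disk0: tuple[int, ...]
    disk1: tuple[int, ...]
    overlap: tuple[int, ...]
    eigenvalue: Optional[float] = None
    gap: Optional[float] = None

    def __post_init__(self) -> None:
        p, d0, d1, ov = (set(self.parent), set(self.disk0),
                         set(self.disk1), set(self.overlap))
        if d0 | d1 != p:
            raise ValueError("disks do not cover the parent")
        if ov != d0 & d1:
            raise ValueError("overlap is not the disk intersection")
        if not (d0 - ov) or not (d1 - ov):
            raise ValueError("empty exclusive region")
        if len(d0) >= len(p) or len(d1) >= len(p):
            raise ValueError("child disk does not shrink")

    @property
    def exclusive0(self) -> tuple[int, ...]:
        ov = set(self.overlap)
        return tuple(i for i in self.disk0 if i not in ov)

    @property
    def exclusive1(self) -> tuple[int, ...]:
        ov = set(self.overlap)
        return tuple(i for i in self.disk1 if i not in ov)


def gaussian_similarity(d: DistanceMatrix, alpha: float) -> SpectralContext:
    """Gaussian similarity graph for one disk's distance matrix."""
    dd = np.asarray(d.d, dtype=float)
    n = dd.shape[0]
    if n < 2:
        raise ValueError("similarity needs at least 2 genomes")
    d_max = float(dd.max())
    if d_max == 0:
        raise DegenerateDiskError("all genomes in the disk are identical")
    sigma = alpha * d_max
    W = np.exp(-(dd ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(W, 0.0)
    D = W.sum(axis=1)
    if np.any(D <= 0):
        raise DegenerateDiskError("zero-degree vertex in similarity graph")
    return SpectralContext(W=W, D=D, sigma=sigma, d_max=d_max)


def build_laplacian(ctx: SpectralContext, kind: str = "random_walk") -> np.ndarray:
    """One of the three standard graph Laplacians of the similarity graph."""
    L = np.diag(ctx.D) - ctx.W
    if kind == "unnormalized":
        return L
    if kind == "symmetric":
        s = 1.0 / np.sqrt(ctx.D)
        return s[:, None] * L * s[None, :]
    if kind == "random_walk":
        return L / ctx.D[:, None]
    raise ValueError(f"unknown laplacian kind {kind!r}")


def fiedler_vector(ctx: SpectralContext, kind: str = "random_walk") -> FiedlerResult:
    """Second-smallest eigenpair of the chosen Laplacian.

    The random-walk spectrum is obtained from the symmetric Laplacian (a
    dense, deterministic symmetric eigensolve) and transformed by
    ``D^(-1/2)``: if (lam, v) is an eigenpair of L_sym, then D^(-1/2) v is
    an eigenvector of L_rw for the same eigenvalue.  The returned vector has
    unit Euclidean norm and its largest-magnitude entry is positive (ties
    broken by lowest index).
    """
    if kind == "unnormalized":
        lam, vecs = scipy.linalg.eigh(build_laplacian(ctx, "unnormalized"))
        vec = vecs[:, 1]
    else:
        lam, vecs = scipy.linalg.eigh(build_laplacian(ctx, "symmetric"))
        vec = vecs[:, 1]
        if kind == "random_walk":
            vec = vec / np.sqrt(ctx.D)
    nrm = float(np.linalg.norm(vec))
    if nrm == 0:  # pragma: no cover - defensive
        raise ArithmeticError("zero Fiedler vector")
    vec = vec / nrm
    k = int(np.argmax(np.abs(vec)))  # first index on ties
    if vec[k] < 0:
        vec = -vec
    return FiedlerResult(eigenvalue=float(lam[1]), vector=vec)


def _fallback_balanced(disk: Sequence[int]) -> DiskDecomposition:
    """Arbitrary balanced split for degenerate disks (all distances zero)."""
    disk = tuple(disk)
    half = len(disk) // 2
    return DiskDecomposition(disk, disk[:half], disk[half:], ())


def _raw_decompose(disk: Sequence[int], d: DistanceMatrix,
                   params: DCMParams) -> DiskDecomposition:
    """Sign/magnitude bipartition of a disk without the big-overlap rewrite."""
    disk = tuple(disk)
    n = len(disk)
    if n < 2:
        raise ValueError("cannot decompose a disk of fewer than 2 genomes")
    sub = d.submatrix(disk)
    try:
        ctx = gaussian_similarity(sub, params.alpha)
    except DegenerateDiskError:
        return _fallback_balanced(disk)
    fied = fiedler_vector(ctx, params.laplacian_kind)
    v = fied.vector

    order = np.argsort(v, kind="stable")  # ascending entries; stable on ties
    neg = [k for k in order if v[k] < 0]
    pos = [k for k in order if v[k] > 0]
    zeros = [k for k in order if v[k] == 0]

    if not neg or not pos:
        # all entries one sign: split off the extreme-entry genome
        ext = int(np.argmax(np.abs(v)))
        rest = tuple(disk[k] for k in range(n) if k != ext)
        return DiskDecomposition(disk, (disk[ext],), rest, (),
                                 eigenvalue=fied.eigenvalue, gap=None)

    gap = float(v[pos[0]] - v[neg[-1]])
    scale = 1.0 / math.sqrt(n)
    overlap: list[int] = list(zeros)  # zero entries carry no confidence
    if gap < params.theta1 * scale:
        cap = int(math.floor(params.max_overlap_fraction * n))
        # walk outward from the boundary on each side until the gap between
        # the current and the next sorted entry exceeds theta2 / sqrt(n)
        for side in (neg[::-1], pos):  # both ordered boundary -> extreme
            for t, k in enumerate(side[:-1]):  # never consume a whole side
                if len(overlap) >= cap:
                    break
                overlap.append(k)
                if abs(v[side[t + 1]] - v[k]) > params.theta2 * scale:
                    break
    ov = set(overlap)
    disk0 = tuple(disk[k] for k in range(n) if v[k] < 0 or k in ov)
    disk1 = tuple(disk[k] for k in range(n) if v[k] > 0 or k in ov)
    return DiskDecomposition(disk, disk0, disk1,
                             tuple(disk[k] for k in sorted(ov)),
                             eigenvalue=fied.eigenvalue, gap=gap)


def avoid_large_overlap(decomp: DiskDecomposition, d: DistanceMatrix,
                        params: DCMParams) -> DiskDecomposition:
    """Rewrite decompositions that dump many central genomes into the overlap.

    When two long edges separate two small outlying groups from a large
    center, the center genomes all get near-zero eigenvector entries and the
    plain walk places them all in the overlap.  The probe re-decomposes each
    child disk: if a child splits into two non-overlapping disks, one of
    which holds the entire parent overlap, the other ("Disk 3") becomes one
    partition and everything else the other, with no overlap at all.
    """
    if not decomp.overlap:
        return decomp
    ov = set(decomp.overlap)
    for child in (decomp.disk0, decomp.disk1):
        if len(child) < 2:
            continue
        sub = _raw_decompose(child, d, params)
        if sub.overlap:
            continue
        for d2, d3 in ((sub.disk0, sub.disk1), (sub.disk1, sub.disk0)):
            if ov <= set(d2):
                rest = tuple(i for i in decomp.parent if i not in set(d3))
                if d3 and rest:
                    return DiskDecomposition(decomp.parent, tuple(d3), rest, (),
                                             eigenvalue=decomp.eigenvalue,
                                             gap=decomp.gap)
    return decomp


def decompose_disk(disk: Sequence[int], d: DistanceMatrix,
                   params: DCMParams) -> DiskDecomposition:
    """One overlap-aware spectral bipartition of a disk of >= 4 genomes."""
    disk = tuple(disk)
    if len(disk) < 4:
        raise ValueError("decompose_disk requires at least 4 genomes")
    return avoid_large_overlap(_raw_decompose(disk, d, params), d, params)


@dataclass
class DiskNode:
    """A node of the binary disk tree: the genome indices it covers, plus the
    decomposition and children when the disk holds more than 3 genomes."""

    indices: tuple[int, ...]
    decomposition: Optional[DiskDecomposition] = None
    children: tuple["DiskNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_disks(self) -> list["DiskNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaf_disks())
        return out

    def all_decompositions(self) -> list[DiskDecomposition]:
        out = [] if self.decomposition is None else [self.decomposition]
        for ch in self.children:
            out.extend(ch.all_decompositions())
        return out

    def to_dict(self) -> dict:
        node: dict = {"size": len(self.indices), "indices": list(self.indices)}
        if self.decomposition is not None:
            node["overlap"] = list(self.decomposition.overlap)
            node["eigenvalue"] = self.decomposition.eigenvalue
            node["gap"] = self.decomposition.gap
            node["children"] = [ch.to_dict() for ch in self.children]
        return node


def build_disk_tree(d: DistanceMatrix, params: Optional[DCMParams] = None,
                    indices: Optional[Sequence[int]] = None) -> DiskNode:
    """Recursively decompose until every leaf disk has at most 3 genomes."""
    params = params or DCMParams()
    idx = tuple(indices) if indices is not None else tuple(range(d.n))
    if len(idx) <= 3:
        return DiskNode(idx)
    decomp = decompose_disk(idx, d, params)
    children = tuple(
        build_disk_tree(d, params, child) for child in (decomp.disk0, decomp.disk1)
    )
    return DiskNode(idx, decomp, children)
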