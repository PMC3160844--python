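"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random
from collections import deque

import numpy as np
import pytest

from spectraldcm import SignedGeneOrder


def bfs_inversion_distance(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Shortest inversion path between two signed permutations, by breadth-
    first search over all inversion moves.  Only feasible for g <= 6."""
    if a == b:
        return 0
    g = len(a)
    invs = [(i, j) for i in range(g) for j in range(i, g)]

    def neighbors(p):
        for i, j in invs:
            yield p[:i] + tuple(-x for x in reversed(p[i:j + 1])) + p[j + 1:]

    seen = {a}
    queue = deque([(a, 0)])
    while queue:
        cur, d = queue.popleft()
        for nxt in neighbors(cur):
            if nxt == b:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise RuntimeError("unreachable")


def exhaustive_median_score(a, b, c) -> int:
    """Minimum summed BFS distance over every signed permutation (tiny g)."""
    g = len(a)
    best = None
    for perm in itertools.permutations(range(1, g + 1)):
        for signs in itertools.product((1, -1), repeat=g):
            m = tuple(p * s for p, s in zip(perm, signs))
            s = (bfs_inversion_distance(m, a) + bfs_inversion_distance(m, b)
                 + bfs_inversion_distance(m, c))
            if best is None or s < best:
                best = s
    return best


def random_signed_perm(g: int, rng: random.Random) -> tuple[int, ...]:
    p = list(range(1, g + 1))
    rng.shuffle(p)
    return tuple(x * rng.choice((1, -1)) for x in p)


def as_genome(name: str, seq) -> SignedGeneOrder:
    return SignedGeneOrder(name, np.array(seq, dtype=np.int32))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260921)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
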