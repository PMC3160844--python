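"""Numba kernels for reversal distance and median-search inner loops.

Everything here operates on raw int32 arrays (signed permutations of
``1..g``); the public API lives in :mod:`spectraldcm.distances` and
:mod:`spectraldcm.medians`.

The reversal distance follows the Hannenhalli-Pevzner theory: express one
genome in the coordinate frame of the other, build the breakpoint graph over
the ``2g+2`` unsigned gene endpoints (framed by ``0`` and ``2g+1``), and
compute

    d = (g + 1) - cycles + hurdles + fortress

where *hurdles* are the unoriented components that are minimal under span
containment plus the greatest one (containing all others) if it exists, and
the *fortress* correction adds 1 when the hurdle count is odd and every
hurdle is a superhurdle.  The component analysis is O(k^2) in the number of
gray edges on nontrivial cycles and only runs when some nontrivial cycle has
no oriented gray edge.

The neighbor scan exploits a structural shortcut: a reversal whose two cut
points fall in *different* cycles of a breakpoint graph with no unoriented
component merges the two cycles and must increase the distance by exactly 1
(cycle count drops by one, no hurdle can appear because a single reversal
changes the distance by at most one).  Such neighbors are scored in O(1),
which removes the vast majority of distance computations from the median
search.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "rev_dist_identity",
    "inverse_map",
    "relabel",
    "rev_dist_pair",
    "scan_all_neighbors",
]


@njit(cache=True)
def _dist_core(gamma, edge_cyc):
    """HP distance of ``gamma`` to identity.

    Fills ``edge_cyc`` (length g+1) with the cycle id of each black edge and
    returns ``(d, clean)`` where ``clean`` means the breakpoint graph has no
    unoriented component.
    """
    g = gamma.shape[0]
    m = 2 * g + 2

    # unsigned doubling with frame markers 0 and 2g+1
    u = np.empty(m, np.int32)
    u[0] = 0
    u[m - 1] = m - 1
    for k in range(g):
        x = gamma[k]
        if x > 0:
            u[2 * k + 1] = 2 * x - 1
            u[2 * k + 2] = 2 * x
        else:
            u[2 * k + 1] = -2 * x
            u[2 * k + 2] = -2 * x - 1
    pos = np.empty(m, np.int32)
    for p in range(m):
        pos[u[p]] = p

    # cycle decomposition: from value v, the black partner sits at the other
    # end of v's black edge (position index xor 1), the gray partner is v^1
    cyc = np.full(m, -1, np.int32)
    ncyc = 0
    for v0 in range(m):
        if cyc[v0] >= 0:
            continue
        v = v0
        while cyc[v] < 0:
            cyc[v] = ncyc
            w = u[pos[v] ^ 1]  # black edge
            cyc[w] = ncyc
            v = w ^ 1  # gray edge
        ncyc += 1
    for i in range(g + 1):
        edge_cyc[i] = cyc[u[2 * i]]

    # per-cycle stats from the g+1 gray edges
    n_gray = g + 1
    elo = np.empty(n_gray, np.int32)
    ehi = np.empty(n_gray, np.int32)
    ecy = np.empty(n_gray, np.int32)
    cyc_black = np.zeros(ncyc, np.int32)
    cyc_oriented = np.zeros(ncyc, np.bool_)
    for i in range(n_gray):
        p = pos[2 * i]
        q = pos[2 * i + 1]
        if p > q:
            p, q = q, p
        c = cyc[2 * i]
        elo[i] = p
        ehi[i] = q
        ecy[i] = c
        cyc_black[c] += 1
        if (q - p) % 2 == 0:
            cyc_oriented[c] = True

    base = (g + 1) - ncyc

    # fast path: every nontrivial cycle carries an oriented gray edge
    need_components = False
    for c in range(ncyc):
        if cyc_black[c] > 1 and not cyc_oriented[c]:
            need_components = True
            break
    if not need_components:
        return base, True

    # keep only gray edges on nontrivial cycles; trivial cycles are
    # adjacencies spanning two consecutive positions and interleave nothing
    nk = 0
    for i in range(n_gray):
        if cyc_black[ecy[i]] > 1:
            nk += 1
    flo = np.empty(nk, np.int32)
    fhi = np.empty(nk, np.int32)
    fcy = np.empty(nk, np.int32)
    t = 0
    for i in range(n_gray):
        if cyc_black[ecy[i]] > 1:
            flo[t] = elo[i]
            fhi[t] = ehi[i]
            fcy[t] = ecy[i]
            t += 1

    # components: union-find over cycles, joined by interleaving gray edges
    parent = np.empty(ncyc, np.int32)
    for c in range(ncyc):
        parent[c] = c
    for i in range(nk):
        for j in range(i + 1, nk):
            if fcy[i] == fcy[j]:
                continue
            if (flo[i] < flo[j] < fhi[i] < fhi[j]) or (
                flo[j] < flo[i] < fhi[j] < fhi[i]
            ):
                ri = _find(parent, fcy[i])
                rj = _find(parent, fcy[j])
                if ri != rj:
                    parent[ri] = rj

    comp_oriented = np.zeros(ncyc, np.bool_)
    comp_lo = np.full(ncyc, m, np.int32)
    comp_hi = np.full(ncyc, -1, np.int32)
    for i in range(nk):
        r = _find(parent, fcy[i])
        if cyc_oriented[fcy[i]]:
            comp_oriented[r] = True
        if flo[i] < comp_lo[r]:
            comp_lo[r] = flo[i]
        if fhi[i] > comp_hi[r]:
            comp_hi[r] = fhi[i]

    # collect unoriented components
    k = 0
    for c in range(ncyc):
        if comp_hi[c] >= 0 and _find(parent, c) == c and not comp_oriented[c]:
            k += 1
    if k == 0:
        return base, True
    ulo = np.empty(k, np.int32)
    uhi = np.empty(k, np.int32)
    t = 0
    for c in range(ncyc):
        if comp_hi[c] >= 0 and _find(parent, c) == c and not comp_oriented[c]:
            ulo[t] = comp_lo[c]
            uhi[t] = comp_hi[c]
            t += 1

    h, f = _hurdles_and_fortress(ulo, uhi)
    return base + h + f, False


@njit(cache=True)
def _find(parent, c):
    while parent[c] != c:
        parent[c] = parent[parent[c]]
        c = parent[c]
    return c


@njit(cache=True)
def _mark_hurdles(ulo, uhi, active, flags):
    """Flag hurdles among the active unoriented components; return the count.

    Hurdles are the span-minimal components plus the greatest component (one
    whose span contains every other active component) when it exists.
    """
    k = ulo.shape[0]
    h = 0
    for i in range(k):
        flags[i] = False
    for i in range(k):
        if not active[i]:
            continue
        minimal = True
        for j in range(k):
            if j != i and active[j] and ulo[i] <= ulo[j] and uhi[j] <= uhi[i]:
                minimal = False
                break
        if minimal:
            flags[i] = True
            h += 1
    for i in range(k):
        if not active[i] or flags[i]:
            continue
        contains_all = True
        for j in range(k):
            if j != i and active[j] and not (ulo[i] <= ulo[j] and uhi[j] <= uhi[i]):
                contains_all = False
                break
        if contains_all:
            flags[i] = True
            h += 1
    return h


@njit(cache=True)
def _hurdles_and_fortress(ulo, uhi):
    k = ulo.shape[0]
    active = np.ones(k, np.bool_)
    flags = np.zeros(k, np.bool_)
    h = _mark_hurdles(ulo, uhi, active, flags)
    if h == 0:
        return 0, 0
    # fortress: odd number of hurdles, all of them superhurdles (deleting a
    # superhurdle promotes some protected non-hurdle into a new hurdle)
    all_super = True
    flags2 = np.zeros(k, np.bool_)
    for i in range(k):
        if not flags[i]:
            continue
        active[i] = False
        _mark_hurdles(ulo, uhi, active, flags2)
        active[i] = True
        is_super = False
        for j in range(k):
            if flags2[j] and not flags[j]:
                is_super = True
                break
        if not is_super:
            all_super = False
            break
    f = 1 if (all_super and h % 2 == 1 and h >= 3) else 0
    return h, f


@njit(cache=True)
def rev_dist_identity(gamma):
    """HP reversal distance from signed permutation ``gamma`` to the identity."""
    edge_cyc = np.empty(gamma.shape[0] + 1, np.int32)
    d, _ = _dist_core(gamma, edge_cyc)
    return d


@njit(cache=True)
def inverse_map(b):
    """Signed inverse of permutation ``b``: map[|x|] = signed position of x."""
    g = b.shape[0]
    m = np.empty(g + 1, np.int32)
    for k in range(g):
        x = b[k]
        if x > 0:
            m[x] = k + 1
        else:
            m[-x] = -(k + 1)
    return m


@njit(cache=True)
def relabel(a, bmap):
    """Express ``a`` in the frame of b, given ``bmap = inverse_map(b)``."""
    g = a.shape[0]
    out = np.empty(g, np.int32)
    for k in range(g):
        y = a[k]
        if y > 0:
            out[k] = bmap[y]
        else:
            out[k] = -bmap[-y]
    return out


@njit(cache=True)
def rev_dist_pair(a, b):
    """HP reversal distance between two signed permutations of the same g."""
    return rev_dist_identity(relabel(a, inverse_map(b)))


@njit(cache=True)
def scan_all_neighbors(q, a, b, c):
    """Distances from every single-inversion neighbor of ``q`` to a, b and c.

    Neighbors are enumerated lexicographically over 0-based inclusive
    inversion windows (i, j), i <= j; entry ``t`` of each returned array is
    the distance from neighbor ``t`` to the respective target.  Neighbors
    whose cut points land in different cycles of a clean (unoriented-free)
    breakpoint graph are scored in O(1) as current distance + 1.
    """
    g = q.shape[0]
    n = g * (g + 1) // 2
    da = np.empty(n, np.int32)
    db = np.empty(n, np.int32)
    dc = np.empty(n, np.int32)

    map_a = inverse_map(a)
    map_b = inverse_map(b)
    map_c = inverse_map(c)
    eca = np.empty(g + 1, np.int32)
    ecb = np.empty(g + 1, np.int32)
    ecc = np.empty(g + 1, np.int32)
    d0a, clean_a = _dist_core(relabel(q, map_a), eca)
    d0b, clean_b = _dist_core(relabel(q, map_b), ecb)
    d0c, clean_c = _dist_core(relabel(q, map_c), ecc)

    w = np.empty(g, np.int32)
    scratch = np.empty(g + 1, np.int32)
    t = 0
    for i in range(g):
        for j in range(i, g):
            made = False
            if clean_a and eca[i] != eca[j + 1]:
                da[t] = d0a + 1
            else:
                if not made:
                    _make_neighbor(q, i, j, w)
                    made = True
                dd, _ = _dist_core(relabel(w, map_a), scratch)
                da[t] = dd
            if clean_b and ecb[i] != ecb[j + 1]:
                db[t] = d0b + 1
            else:
                if not made:
                    _make_neighbor(q, i, j, w)
                    made = True
                dd, _ = _dist_core(relabel(w, map_b), scratch)
                db[t] = dd
            if clean_c and ecc[i] != ecc[j + 1]:
                dc[t] = d0c + 1
            else:
                if not made:
                    _make_neighbor(q, i, j, w)
                    made = True
                dd, _ = _dist_core(relabel(w, map_c), scratch)
                dc[t] = dd
            t += 1
    return da, db, dc


@njit(cache=True)
def _make_neighbor(q, i, j, w):
    g = q.shape[0]
    for k in range(g):
        w[k] = q[k]
    lo = i
    hi = j
    while lo <= hi:  # lo == hi negates the middle element in place
        tmp = w[lo]
        w[lo] = -w[hi]
        w[hi] = -tmp
        lo += 1
        hi -= 1
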