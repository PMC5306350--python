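"""Numba-compiled inner loop of the cooperative motion algorithm.

The kernel mirrors, draw for draw, the pure-Python move logic in
:mod:`cmapoly.engine` (same PCG32 stream, same walk-closure and
bond-check rules), so the two can be cross-checked bitwise on small
systems while production runs use the compiled path.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

U64 = np.uint64
_MULT = U64(6364136223846793005)
_INC = U64(1442695040888963407)
_M32 = U64(0xFFFFFFFF)

# direction tables; order must match lattice.IN_PLANE_DIRECTIONS
_DIR_A = np.array([1, -1, 0, 0, 1, -1], dtype=np.int64)
_DIR_B = np.array([0, 0, 1, -1, -1, 1], dtype=np.int64)


@njit(cache=True, inline="always")
def _next_u32(rng):
    old = rng[0]
    rng[0] = old * _MULT + _INC
    xs = (((old >> U64(18)) ^ old) >> U64(27)) & _M32
    rot = old >> U64(59)
    return ((xs >> rot) | (xs << ((U64(32) - rot) & U64(31)))) & _M32


@njit(cache=True, inline="always")
def _bounded(rng, n):
    """Unbiased integer in [0, n) by rejection (matches rng.Pcg32.bounded)."""
    nn = U64(n)
    limit = U64(4294967296) - (U64(4294967296) % nn)
    while True:
        r = _next_u32(rng)
        if r < limit:
            return np.int64(r % nn)


@njit(cache=True, inline="always")
def _neighbor(s, d, L, LL):
    layer = s // LL
    rem = s - layer * LL
    b = rem // L
    a = rem - b * L
    if d == 6:  # mirror site in the other layer
        return (1 - layer) * LL + rem
    a2 = (a + _DIR_A[d]) % L
    b2 = (b + _DIR_B[d]) % L
    return layer * LL + b2 * L + a2


@njit(cache=True, inline="always")
def _adjacent(s1, s2, L, LL):
    l1 = s1 // LL
    l2 = s2 // LL
    r1 = s1 - l1 * LL
    r2 = s2 - l2 * LL
    if l1 != l2:
        return r1 == r2
    b1 = r1 // L
    b2 = r2 // L
    da = (r2 - b2 * L - (r1 - b1 * L)) % L
    db = (b2 - b1) % L
    if da == 1 and db == 0:
        return True
    if da == L - 1 and db == 0:
        return True
    if da == 0 and db == 1:
        return True
    if da == 0 and db == L - 1:
        return True
    if da == 1 and db == L - 1:
        return True
    if da == L - 1 and db == 1:
        return True
    return False


@njit(cache=True, inline="always")
def _cycle_pos(c, b, cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site):
    """Current position of bonded partner (c, b): overlaid if it is a
    cycle element, else from the global table.  ``moved[i]`` true means
    element i already sits at cyc_sites[(i-1) % k]."""
    for i in range(k):
        if cyc_chain[i] == c and cyc_bead[i] == b:
            if moved[i]:
                return cyc_sites[i - 1] if i > 0 else cyc_sites[k - 1]
            return cyc_sites[i]
    return np.int64(bead_site[c, b])


@njit(cache=True, inline="always")
def _fits(c, b, site, N, L, LL, cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site):
    if c < 0:
        return True
    if b > 0:
        p = _cycle_pos(c, b - 1, cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site)
        if not _adjacent(site, p, L, LL):
            return False
    if b < N - 1:
        p = _cycle_pos(c, b + 1, cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site)
        if not _adjacent(site, p, L, LL):
            return False
    return True


@njit(cache=True)
def _rotation_probability_sum(
    cyc_sites, cyc_chain, cyc_bead, k, occ_chain, occ_bead, bead_site, N, L, LL, n_dirs, moved
):
    """Summed generation probability of the cycle over its k rotations
    (mirrors engine._rotation_probability_sum)."""
    total = 0.0
    for r in range(k):
        for i in range(k):
            moved[i] = False
        prob = 1.0
        feasible = True
        for t in range(1, k + 1):
            w = cyc_sites[(r + t - 1) % k]
            n_cand = 0
            prescribed_ok = False
            prescribed_site = cyc_sites[(r + t) % k] if t < k else np.int64(-1)
            for d in range(n_dirs):
                u = _neighbor(w, d, L, LL)
                if u == cyc_sites[r]:
                    if t >= 3 and _fits(
                        cyc_chain[r], cyc_bead[r], w, N, L, LL,
                        cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site,
                    ):
                        n_cand += 1
                        if t == k:
                            prescribed_ok = True
                    continue
                idx = -1
                for i in range(k):
                    if cyc_sites[i] == u:
                        idx = i
                        break
                if idx >= 0 and (idx - r) % k < t:
                    continue  # visited vacancy path site
                if idx >= 0:
                    c = cyc_chain[idx]
                    b = cyc_bead[idx]
                else:
                    c = occ_chain[u]
                    b = occ_bead[u]
                if c < 0 or _fits(
                    c, b, w, N, L, LL,
                    cyc_chain, cyc_bead, cyc_sites, moved, k, bead_site,
                ):
                    n_cand += 1
                    if t < k and u == prescribed_site:
                        prescribed_ok = True
            if not prescribed_ok or n_cand == 0:
                feasible = False
                break
            prob /= n_cand
            if t < k:
                moved[(r + t) % k] = True
        if feasible:
            total += prob
    return total


@njit(cache=True, inline="always")
def _fits_walk(c, b, site, N, L, LL, cyc_chain, cyc_bead, cyc_sites, k_walk, bead_site):
    """Bond check during walk generation: elements 1..k_walk-1 have been
    pulled and sit at cyc_sites[i-1]; everything else is at bead_site."""
    if c < 0:
        return True
    for off in (-1, 1):
        nb = b + off
        if 0 <= nb < N:
            p = np.int64(bead_site[c, nb])
            for i in range(1, k_walk):
                if cyc_chain[i] == c and cyc_bead[i] == nb:
                    p = cyc_sites[i - 1]
                    break
            if not _adjacent(site, p, L, LL):
                return False
    return True


@njit(cache=True)
def run_attempts_guided(
    occ_chain,
    occ_bead,
    bead_site,
    L,
    layers,
    n_dirs,
    max_len,
    target_displacements,
    rng,
    counters,
    mark,
    stamp_box,
    loop_hist,
):
    """Guided-walk counterpart of :func:`run_attempts` (same interface)."""
    LL = L * L
    n_sites = layers * LL
    N = bead_site.shape[1]
    cyc_sites = np.empty(max_len + 1, dtype=np.int64)
    cyc_chain = np.empty(max_len + 1, dtype=np.int32)
    cyc_bead = np.empty(max_len + 1, dtype=np.int32)
    moved = np.zeros(max_len + 1, dtype=np.bool_)
    cand_site = np.empty(8, dtype=np.int64)
    cand_close = np.empty(8, dtype=np.bool_)

    while counters[0] < target_displacements:
        counters[1] += 1
        stamp_box[0] += 1
        stamp = stamp_box[0]
        v0 = _bounded(rng, n_sites)
        cyc_sites[0] = v0
        cyc_chain[0] = occ_chain[v0]
        cyc_bead[0] = occ_bead[v0]
        mark[v0] = stamp
        k = 1
        w = v0
        closed = False
        while True:
            counters[0] += 1
            # enumerate legal continuations at vacancy w
            n_cand = 0
            for d in range(n_dirs):
                u = _neighbor(w, d, L, LL)
                if u == v0:
                    if k >= 3 and _fits_walk(
                        cyc_chain[0], cyc_bead[0], w, N, L, LL,
                        cyc_chain, cyc_bead, cyc_sites, k, bead_site,
                    ):
                        cand_site[n_cand] = u
                        cand_close[n_cand] = True
                        n_cand += 1
                elif mark[u] != stamp:
                    c = occ_chain[u]
                    b = occ_bead[u]
                    if _fits_walk(
                        c, b, w, N, L, LL,
                        cyc_chain, cyc_bead, cyc_sites, k, bead_site,
                    ):
                        cand_site[n_cand] = u
                        cand_close[n_cand] = False
                        n_cand += 1
            if n_cand == 0:
                break
            pick = _bounded(rng, n_cand)
            u = cand_site[pick]
            if cand_close[pick]:
                closed = True
                break
            cyc_sites[k] = u
            cyc_chain[k] = occ_chain[u]
            cyc_bead[k] = occ_bead[u]
            mark[u] = stamp
            k += 1
            w = u
            if k >= max_len:
                break
        if not closed:
            continue
        any_bead = False
        for t in range(k):
            if cyc_chain[t] >= 0:
                any_bead = True
                break
        if not any_bead:
            continue  # all-solvent cycle: a physical no-op

        s_fwd = _rotation_probability_sum(
            cyc_sites, cyc_chain, cyc_bead, k,
            occ_chain, occ_bead, bead_site, N, L, LL, n_dirs, moved,
        )
        # apply: element t moves cyc_sites[t] -> cyc_sites[t-1]; elem 0 -> last
        for t in range(1, k):
            c = cyc_chain[t]
            b = cyc_bead[t]
            dest = cyc_sites[t - 1]
            occ_chain[dest] = c
            occ_bead[dest] = b
            if c >= 0:
                bead_site[c, b] = np.int32(dest)
        dest = cyc_sites[k - 1]
        occ_chain[dest] = cyc_chain[0]
        occ_bead[dest] = cyc_bead[0]
        if cyc_chain[0] >= 0:
            bead_site[cyc_chain[0], cyc_bead[0]] = np.int32(dest)

        # reversed cycle, element positions as they now stand
        rev_sites = np.empty(k, dtype=np.int64)
        rev_chain = np.empty(k, dtype=np.int32)
        rev_bead = np.empty(k, dtype=np.int32)
        for t in range(k):
            rev_sites[t] = cyc_sites[k - 1 - t]
        rev_chain[0] = cyc_chain[0]
        rev_bead[0] = cyc_bead[0]
        for t in range(1, k):
            rev_chain[t] = cyc_chain[k - t]
            rev_bead[t] = cyc_bead[k - t]
        s_rev = _rotation_probability_sum(
            rev_sites, rev_chain, rev_bead, k,
            occ_chain, occ_bead, bead_site, N, L, LL, n_dirs, moved,
        )
        if (_next_u32(rng) / 4294967296.0) * s_fwd < s_rev:
            counters[2] += 1
            h = k if k < loop_hist.shape[0] else loop_hist.shape[0] - 1
            loop_hist[h] += 1
        else:
            for t in range(k):
                c = cyc_chain[t]
                b = cyc_bead[t]
                occ_chain[cyc_sites[t]] = c
                occ_bead[cyc_sites[t]] = b
                if c >= 0:
                    bead_site[c, b] = np.int32(cyc_sites[t])


@njit(cache=True)
def run_attempts(
    occ_chain,
    occ_bead,
    bead_site,
    L,
    layers,
    n_dirs,
    max_len,
    target_displacements,
    rng,
    counters,
    mark,
    stamp_box,
    loop_hist,
):
    """Advance the system until the cumulative attempted-displacement
    counter reaches ``target_displacements``.

    counters = [displacements, walk attempts, accepted loops]; ``mark`` is
    a per-site visit stamp (timestamp trick, never cleared); ``loop_hist``
    counts accepted loops by length (index ``min(k, len-1)``).
    """
    LL = L * L
    n_sites = layers * LL
    N = bead_site.shape[1]
    path = np.empty(max_len + 1, dtype=np.int64)
    save_chain = np.empty(max_len + 1, dtype=np.int32)
    save_bead = np.empty(max_len + 1, dtype=np.int32)

    while counters[0] < target_displacements:
        counters[1] += 1
        stamp_box[0] += 1
        stamp = stamp_box[0]
        s0 = _bounded(rng, n_sites)
        path[0] = s0
        mark[s0] = stamp
        k = 1
        cur = s0
        closed = False
        while True:
            d = _bounded(rng, n_dirs)
            nxt = _neighbor(cur, d, L, LL)
            counters[0] += 1
            if nxt == s0:
                closed = k >= 3  # a 2-site swap is not a cooperative loop
                break
            if mark[nxt] == stamp:
                break  # self-intersecting walk: reject
            if k >= max_len:
                break
            path[k] = nxt
            mark[nxt] = stamp
            k += 1
            cur = nxt
        if not closed:
            continue

        # tentative cyclic permutation: element at path[i] -> path[i+1]
        for i in range(k):
            save_chain[i] = occ_chain[path[i]]
            save_bead[i] = occ_bead[path[i]]
        for i in range(k):
            j = i + 1 if i + 1 < k else 0
            c = save_chain[i]
            occ_chain[path[j]] = c
            occ_bead[path[j]] = save_bead[i]
            if c >= 0:
                bead_site[c, save_bead[i]] = np.int32(path[j])

        ok = True
        for i in range(k):
            c = save_chain[i]
            if c < 0:
                continue
            bi = save_bead[i]
            if bi > 0 and not _adjacent(
                np.int64(bead_site[c, bi - 1]), np.int64(bead_site[c, bi]), L, LL
            ):
                ok = False
                break
            if bi < N - 1 and not _adjacent(
                np.int64(bead_site[c, bi]), np.int64(bead_site[c, bi + 1]), L, LL
            ):
                ok = False
                break

        if ok:
            counters[2] += 1
            h = k if k < loop_hist.shape[0] else loop_hist.shape[0] - 1
            loop_hist[h] += 1
        else:
            for i in range(k):
                c = save_chain[i]
                occ_chain[path[i]] = c
                occ_bead[path[i]] = save_bead[i]
                if c >= 0:
                    bead_site[c, save_bead[i]] = np.int32(path[i])
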