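"""Low-level numba kernels shared by the index, MEM finder and extension code.

All kernels operate on integer-encoded text: nucleotides are small positive
codes (see :mod:`memclust.suffix_index`), sequence terminators are distinct
negative values.  Two conventions are enforced everywhere:

* ``N`` (code ``N_CODE``) never matches anything, including another ``N`` —
  identity through assembly gaps is meaningless;
* terminators are pairwise distinct, so a plain equality test can never run
  across a sequence boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: encoded value of the ambiguity base N (must agree with suffix_index.ENCODE)
N_CODE = 4


@njit(cache=True, nogil=True)
def match_len(text, p, query, q):
    """Length of the maximal exact match extension to the right of (p, q).

    Stops at the first mismatch, at an N on either side, at a terminator
    (negative code) or at the end of either array.
    """
    n, m = text.size, query.size
    l = 0
    while p + l < n and q + l < m:
        a = text[p + l]
        b = query[q + l]
        if a != b or a == N_CODE or a < 0:
            break
        l += 1
    return l


@njit(cache=True, nogil=True)
def plain_lcp(text, a, b):
    """Longest common prefix of two suffixes of ``text`` by direct comparison.

    Plain character equality: used for the LCP array, where N == N counts as
    equal (it is a statement about the text, not about match semantics).
    Terminators are pairwise distinct so comparisons still never cross them.
    """
    n = text.size
    l = 0
    while a + l < n and b + l < n and text[a + l] == text[b + l]:
        l += 1
    return l


@njit(cache=True, nogil=True)
def _cmp_suffix_window(text, p, query, q, tau):
    """Lexicographic comparison of text[p:] against query[q:q+tau].

    Returns -1 / 0 / +1 for suffix < window / window is a prefix of the
    suffix / suffix > window.  A suffix that ends early is smaller.
    """
    n = text.size
    for i in range(tau):
        if p + i >= n:
            return -1
        a = text[p + i]
        b = query[q + i]
        if a < b:
            return -1
        if a > b:
            return 1
    return 0


@njit(cache=True, nogil=True)
def window_bounds(text, sa, query, q, tau):
    """SA interval [lo, hi) of sampled suffixes having query[q:q+tau] as prefix."""
    nsa = sa.size
    lo = 0
    hi = nsa
    while lo < hi:
        mid = (lo + hi) // 2
        if _cmp_suffix_window(text, sa[mid], query, q, tau) < 0:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    hi = nsa
    while lo < hi:
        mid = (lo + hi) // 2
        if _cmp_suffix_window(text, sa[mid], query, q, tau) <= 0:
            lo = mid + 1
        else:
            hi = mid
    return first, lo


@njit(cache=True, nogil=True)
def adjacent_lcp(text, sa):
    """LCP array for (a possibly sparse) suffix array: LCP[0] = 0."""
    lcp = np.zeros(sa.size, dtype=np.int64)
    for i in range(1, sa.size):
        lcp[i] = plain_lcp(text, sa[i - 1], sa[i])
    return lcp


@njit(cache=True, nogil=True)
def next_n_positions(query):
    """nn[i] = smallest j >= i with query[j] == N (query.size if none)."""
    m = query.size
    nn = np.empty(m + 1, dtype=np.int64)
    nn[m] = m
    for i in range(m - 1, -1, -1):
        if query[i] == N_CODE:
            nn[i] = i
        else:
            nn[i] = nn[i + 1]
    return nn


@njit(cache=True, nogil=True)
def mem_scan(text, sa, pos_member, member_start, member_len, K, L, query,
             min_member_len, out):
    """Enumerate all MEMs of length >= L between ``query`` and the indexed text.

    For every query position q the window query[q:q+tau] (tau = L-K+1) is
    located in the sampled suffix array by binary search; every sampled suffix
    in the interval is right-extended to its full match length and verified
    for left-maximality by scanning at most K-1 characters leftward.  A match
    is emitted only from the first sampled reference position it contains, so
    each MEM is reported exactly once.

    ``out`` is an (cap, 4) int64 array receiving rows
    (member_index, ref_offset_in_member, query_start, length).  Returns the
    number of MEMs found; if that exceeds ``out.shape[0]`` the caller must
    retry with a larger buffer (rows beyond the capacity are counted, not
    written).
    """
    tau = L - K + 1
    m = query.size
    cap = out.shape[0]
    n_out = 0
    if m < L:
        return 0
    nn = next_n_positions(query)
    for q in range(m - tau + 1):
        if nn[q] < q + tau:
            continue  # window contains N: no MEM can be anchored here
        lo, hi = window_bounds(text, sa, query, q, tau)
        for idx in range(lo, hi):
            p = sa[idx]
            # left verification: emit only from the first sampled anchor
            e = 0
            while e < K and p - e - 1 >= 0 and q - e - 1 >= 0:
                a = text[p - e - 1]
                if a != query[q - e - 1] or a == N_CODE or a < 0:
                    break
                e += 1
            if e == K:
                continue  # p-K is a sampled anchor of the same MEM
            l = match_len(text, p, query, q)
            length = e + l
            if length < L:
                continue
            mem = pos_member[p]
            if member_len[mem] < min_member_len:
                continue
            if n_out < cap:
                out[n_out, 0] = mem
                out[n_out, 1] = (p - e) - member_start[mem]
                out[n_out, 2] = q - e
                out[n_out, 3] = length
            n_out += 1
    return n_out


@njit(cache=True, nogil=True)
def brute_mems(ref, query, L, out):
    """Quadratic diagonal run-length MEM enumeration (test oracle).

    ``ref`` and ``query`` are encoded arrays without terminators.  Emits rows
    (ref_start, query_start, length) for every maximal run of matching,
    non-N characters of length >= L.  Returns the count (same overflow
    convention as :func:`mem_scan`).
    """
    n, m = ref.size, query.size
    cap = out.shape[0]
    n_out = 0
    for d in range(-(n - 1), m):
        if d >= 0:
            ri, qi = 0, d
        else:
            ri, qi = -d, 0
        run = 0
        while ri < n and qi < m:
            a = ref[ri]
            if a == query[qi] and a != N_CODE:
                run += 1
            else:
                if run >= L:
                    if n_out < cap:
                        out[n_out, 0] = ri - run
                        out[n_out, 1] = qi - run
                        out[n_out, 2] = run
                    n_out += 1
                run = 0
            ri += 1
            qi += 1
        if run >= L:
            if n_out < cap:
                out[n_out, 0] = ri - run
                out[n_out, 1] = qi - run
                out[n_out, 2] = run
            n_out += 1
    return n_out


@njit(cache=True, nogil=True)
def xdrop_ungapped(a, b, match, mismatch, xdrop):
    """Ungapped x-drop extension along two equal-direction windows.

    ``a`` and ``b`` are the flank windows, already oriented so index 0 is the
    first position to consume (callers reverse them for leftward extension).
    Advances while the running score stays within ``xdrop`` of the best score
    seen; returns (steps, n_match, score) of the best-scoring prefix, ties
    broken in favour of the longer prefix (more matched bases).
    """
    limit = min(a.size, b.size)
    score = 0
    nmatch = 0
    best = 0
    best_t = 0
    best_n = 0
    for t in range(limit):
        ca = a[t]
        if ca == b[t] and ca != N_CODE and ca >= 0:
            score += match
            nmatch += 1
        else:
            score += mismatch
        if score >= best:  # >= : prefer the longer prefix on score ties
            best = score
            best_t = t + 1
            best_n = nmatch
        elif best - score >= xdrop:
            break
    return best_t, best_n, best


@njit(cache=True, nogil=True)
def xdrop_gapped(a, b, match, mismatch, gap_open, gap_extend, xdrop):
    """Affine-gap x-drop extension along two windows (banded wavefront).

    Dynamic program over antidiagonals d = i + j where i (j) counts characters
    consumed from ``a`` (``b``).  Three states: M (last column aligned a char
    against a char), GA (gap in ``b``), GB (gap in ``a``); ``gap_open`` is the
    cost of the first gapped base, ``gap_extend`` of each further one.  Cells
    whose best state falls ``xdrop`` below the running best score are pruned;
    extension stops when an antidiagonal has no live cell.

    Returns (i, j, n_match, score) of the best endpoint; ties prefer more
    matched bases, then the shorter extension, deterministically.
    """
    la, lb = a.size, b.size
    NEG = np.int64(-(1 << 40))
    size = la + 1
    # state score / match-count arrays for diagonals d-2, d-1 (rotated)
    m2 = np.full(size, NEG, np.int64)
    ga2 = np.full(size, NEG, np.int64)
    gb2 = np.full(size, NEG, np.int64)
    cm2 = np.zeros(size, np.int64)
    cga2 = np.zeros(size, np.int64)
    cgb2 = np.zeros(size, np.int64)
    m1 = np.full(size, NEG, np.int64)
    ga1 = np.full(size, NEG, np.int64)
    gb1 = np.full(size, NEG, np.int64)
    cm1 = np.zeros(size, np.int64)
    cga1 = np.zeros(size, np.int64)
    cgb1 = np.zeros(size, np.int64)

    m2[0] = 0  # d = 0: empty extension, M state, score 0
    best = np.int64(0)
    best_i = 0
    best_j = 0
    best_n = 0
    lo1, hi1 = 0, 0  # live i-range on diagonal d-1 (currently d=0 in m2... )
    # initialize: treat diagonal 0 as "d-1" for the first iteration
    m1, m2 = m2, m1
    ga1, ga2 = ga2, ga1
    gb1, gb2 = gb2, gb1
    cm1, cm2 = cm2, cm1
    lo2, hi2 = 0, -1  # d-2 empty before d=1

    for d in range(1, la + lb + 1):
        lo = max(0, d - lb, min(lo1, lo2 + 1))
        hi = min(la, d, max(hi1 + 1, hi2 + 1))
        if lo > hi:
            break
        mc = np.full(size, NEG, np.int64)
        gac = np.full(size, NEG, np.int64)
        gbc = np.full(size, NEG, np.int64)
        cmc = np.zeros(size, np.int64)
        cgac = np.zeros(size, np.int64)
        cgbc = np.zeros(size, np.int64)
        any_live = False
        new_lo = hi + 1
        new_hi = lo - 1
        for i in range(lo, hi + 1):
            j = d - i
            # M: consume a[i-1] vs b[j-1] from best state at (i-1, j-1), d-2
            if i >= 1 and j >= 1:
                ps = m2[i - 1]
                pn = cm2[i - 1]
                if ga2[i - 1] > ps or (ga2[i - 1] == ps and cga2[i - 1] > pn):
                    ps = ga2[i - 1]
                    pn = cga2[i - 1]
                if gb2[i - 1] > ps or (gb2[i - 1] == ps and cgb2[i - 1] > pn):
                    ps = gb2[i - 1]
                    pn = cgb2[i - 1]
                if ps > NEG:
                    ca = a[i - 1]
                    if ca == b[j - 1] and ca != N_CODE and ca >= 0:
                        mc[i] = ps + match
                        cmc[i] = pn + 1
                    else:
                        mc[i] = ps + mismatch
                        cmc[i] = pn
            # GA: consume a[i-1] only, from (i-1, j), d-1
            if i >= 1:
                o = m1[i - 1]
                on = cm1[i - 1]
                if gb1[i - 1] > o or (gb1[i - 1] == o and cgb1[i - 1] > on):
                    o = gb1[i - 1]
                    on = cgb1[i - 1]
                sc_open = o + gap_open if o > NEG else NEG
                sc_ext = ga1[i - 1] + gap_extend if ga1[i - 1] > NEG else NEG
                if sc_open >= sc_ext:
                    if sc_open > NEG:
                        gac[i] = sc_open
                        cgac[i] = on
                else:
                    gac[i] = sc_ext
                    cgac[i] = cga1[i - 1]
            # GB: consume b[j-1] only, from (i, j-1), d-1
            if j >= 1:
                o = m1[i]
                on = cm1[i]
                if ga1[i] > o or (ga1[i] == o and cga1[i] > on):
                    o = ga1[i]
                    on = cga1[i]
                sc_open = o + gap_open if o > NEG else NEG
                sc_ext = gb1[i] + gap_extend if gb1[i] > NEG else NEG
                if sc_open >= sc_ext:
                    if sc_open > NEG:
                        gbc[i] = sc_open
                        cgbc[i] = on
                else:
                    gbc[i] = sc_ext
                    cgbc[i] = cgb1[i]
            # x-drop pruning on the cell's best state
            h = mc[i]
            hn = cmc[i]
            if gac[i] > h:
                h = gac[i]
                hn = cgac[i]
            if gbc[i] > h:
                h = gbc[i]
                hn = cgbc[i]
            if h <= NEG or best - h >= xdrop:
                mc[i] = NEG
                gac[i] = NEG
                gbc[i] = NEG
                continue
            any_live = True
            if i < new_lo:
                new_lo = i
            if i > new_hi:
                new_hi = i
            # endpoint candidates: only M-state ends are meaningful (a
            # trailing gap adds penalty and no matches)
            if mc[i] > NEG and (
                mc[i] > best or (mc[i] == best and cmc[i] > best_n)
            ):
                best = mc[i]
                best_n = cmc[i]
                best_i = i
                best_j = j
        if not any_live:
            break
        m2, m1 = m1, mc
        ga2, ga1 = ga1, gac
        gb2, gb1 = gb1, gbc
        cm2, cm1 = cm1, cmc
        cga2, cga1 = cga1, cgac
        cgb2, cgb1 = cgb1, cgbc
        lo2, hi2 = lo1, hi1
        lo1, hi1 = new_lo, new_hi
    return best_i, best_j, best_n, best
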