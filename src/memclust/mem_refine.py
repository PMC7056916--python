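"""MEM refinement, score-matrix extension, and the eMEM identity statistic.

Raw MEM sets between one (representative, query, strand) pair overlap and
nest freely.  Refinement reduces them to segments whose projections onto
*both* sequences are pairwise disjoint, in four steps:

(A) remove MEMs contained in a single larger MEM (on either projection);
(B) remove MEMs covered by the union of their two flanking neighbours;
(C) trim partial overlaps right-to-left, shifting the start of the current
    MEM on both sequences by the overlap amount;
(D) extend the surviving segments outward under an x-drop rule, clipped at
    the midpoint of the gap to each neighbour so projections stay disjoint.

The identity between the two sequences is then

    eMEMi = Nmatch / Lquery

where Nmatch is the number of matched bases inside the extended segments
and Lquery the length of the shorter (query) sequence.

All coordinates must be in the frame in which the match content is
collinear: for minus-strand MEM groups that is the reverse-complemented
query frame (the clustering engine handles the conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .mem_finder import MEM
from .suffix_index import encode

__all__ = [
    "ScoreScheme",
    "ExtendedMatch",
    "IdentityResult",
    "remove_contained",
    "trim_overlaps",
    "extend_matches",
    "compute_ememi",
    "refine_and_extend",
]


@dataclass(frozen=True)
class ScoreScheme:
    """Scores for seed extension.

    These are configuration, not measured quantities: +1/-1 with small
    affine gap costs and a drop-off of 5 follow common seed-extension
    practice.  ``xdrop`` is the amount the running score may fall below the
    best score seen before extension stops.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    xdrop: int = 5
    gapped: bool = False

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be < 0")
        if self.gap_open >= 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be negative")
        if self.xdrop <= 0:
            raise ValueError("xdrop must be > 0")


@dataclass(frozen=True)
class ExtendedMatch:
    """A refined MEM after extension (an eMEM), with its matched-base count."""

    source: MEM
    ext_ref_span: tuple[int, int]
    ext_query_span: tuple[int, int]
    n_match: int


@dataclass(frozen=True)
class IdentityResult:
    ememi: float
    n_match_total: int
    l_query: int
    strand: str = "+"


def _contains(outer_start: int, outer_end: int, start: int, end: int) -> bool:
    return outer_start <= start and end <= outer_end


def _covered_by_union(s: int, e: int, s1: int, e1: int, s2: int, e2: int) -> bool:
    """Is [s, e) covered by [s1, e1) ∪ [s2, e2)?"""
    if _contains(s1, e1, s, e) or _contains(s2, e2, s, e):
        return True
    if s1 > s2:
        s1, e1, s2, e2 = s2, e2, s1, e1
    return s1 <= s and e <= e2 and e1 >= s2


def remove_contained(mems: list[MEM]) -> list[MEM]:
    """Drop MEMs swallowed by a larger MEM or by two flanking neighbours.

    Containment is tested on the representative projection *and* on the
    query projection (either suffices for removal).  Output is sorted by
    representative start.  All input MEMs must belong to one
    (representative, query, strand) triple.
    """
    mems = sorted(mems, key=lambda m: (m.ref_start, -m.length, m.query_start))
    n = len(mems)
    if n <= 1:
        return mems
    # (A) contained in a single larger MEM
    keep: list[MEM] = []
    for i, m in enumerate(mems):
        swallowed = False
        for j, other in enumerate(mems):
            if j == i or other.length < m.length:
                continue
            if other.length == m.length and j >= i:
                continue  # equal length: earlier-sorted MEM wins, no mutual kill
            if _contains(other.ref_start, other.ref_end, m.ref_start, m.ref_end) or _contains(
                other.query_start, other.query_end, m.query_start, m.query_end
            ):
                swallowed = True
                break
        if not swallowed:
            keep.append(m)
    # (B) covered by the union of the two flanking neighbours (ref-start order)
    result: list[MEM] = []
    for i, m in enumerate(keep):
        prev = result[-1] if result else None
        nxt = keep[i + 1] if i + 1 < len(keep) else None
        if prev is not None and nxt is not None:
            if _covered_by_union(
                m.ref_start, m.ref_end, prev.ref_start, prev.ref_end, nxt.ref_start, nxt.ref_end
            ) or _covered_by_union(
                m.query_start,
                m.query_end,
                prev.query_start,
                prev.query_end,
                nxt.query_start,
                nxt.query_end,
            ):
                continue
        result.append(m)
    return result


def _trim_pass(mems: list[MEM], key: str) -> tuple[list[MEM], bool]:
    """One right-to-left trim sweep in ``key`` (ref/query) start order."""
    if key == "ref":
        mems = sorted(mems, key=lambda m: (m.ref_start, m.query_start))
    else:
        mems = sorted(mems, key=lambda m: (m.query_start, m.ref_start))
    out = list(mems)
    changed = False
    for i in range(len(out) - 1, 0, -1):
        left = out[i - 1]
        cur = out[i]
        ov = max(left.ref_end - cur.ref_start, left.query_end - cur.query_start, 0)
        if ov > 0:
            changed = True
            out[i] = replace(
                cur,
                ref_start=cur.ref_start + ov,
                query_start=cur.query_start + ov,
                length=cur.length - ov,
            )
    return [m for m in out if m.length >= 1], changed


def trim_overlaps(mems: list[MEM]) -> list[MEM]:
    """Trim partial overlaps so both projections become pairwise disjoint.

    Right-to-left sweep in representative-start order: where the current MEM
    overlaps its left neighbour on either sequence, its start coordinates on
    both sequences shift rightward by the overlap amount (length shrinks
    equally); MEMs falling below one base are dropped.  The sweep alternates
    with the same sweep in query-start order until neither changes anything:
    crossing (non-collinear) or nested survivors can expose an overlap to a
    new neighbour only after an intervening MEM was trimmed away, and each
    change strictly shrinks total span length, so the alternation terminates.
    At the fixpoint, adjacent spans are disjoint in both sort orders, which
    for start-sorted intervals implies pairwise disjointness on both
    projections.
    """
    out = list(mems)
    changed = True
    while changed:
        out, c1 = _trim_pass(out, "ref")
        out, c2 = _trim_pass(out, "query")
        changed = c1 or c2
    return sorted(out, key=lambda m: m.ref_start)


def _midpoint_limits(spans: list[tuple[int, int]], total: int) -> list[tuple[int, int]]:
    """Per-span (left_allowance, right_allowance) halving each inter-span gap."""
    order = sorted(range(len(spans)), key=lambda i: spans[i])
    limits = [(0, 0)] * len(spans)
    for rank, i in enumerate(order):
        s, e = spans[i]
        if rank == 0:
            left = s
        else:
            gap = s - spans[order[rank - 1]][1]
            left = gap // 2
        if rank == len(order) - 1:
            right = total - e
        else:
            gap = spans[order[rank + 1]][0] - e
            right = gap - gap // 2
        limits[i] = (left, right)
    return limits


def _extend_one_side(
    ra: np.ndarray, qa: np.ndarray, scheme: ScoreScheme
) -> tuple[int, int, int]:
    """Best (ref_steps, query_steps, n_match) extension into two flank windows.

    Ungapped mode advances both windows in lockstep under the x-drop rule.
    Gapped mode additionally runs a banded affine-gap x-drop extension and
    keeps whichever endpoint recovers more matched bases (score breaks
    ties), so a gapped extension never recovers fewer matches than the
    ungapped one on the same seed.
    """
    t, n, s = _kernels.xdrop_ungapped(ra, qa, scheme.match, scheme.mismatch, scheme.xdrop)
    if not scheme.gapped:
        return t, t, n
    gi, gj, gn, gs = _kernels.xdrop_gapped(
        ra, qa, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend, scheme.xdrop
    )
    if (gn, gs) >= (n, s):
        return gi, gj, gn
    return t, t, n


def extend_matches(
    mems: list[MEM],
    rep_seq: str | np.ndarray,
    query_seq: str | np.ndarray,
    scheme: ScoreScheme | None = None,
) -> list[ExtendedMatch]:
    """Extend refined (disjoint) MEMs outward with the score scheme.

    Extensions are clipped at the midpoint of the gap to the neighbouring
    segment on each projection, so the extended projections remain pairwise
    disjoint and no base can be counted twice by :func:`compute_ememi`.
    """
    if scheme is None:
        scheme = ScoreScheme()
    if not mems:
        return []
    rep = encode(rep_seq) if isinstance(rep_seq, str) else rep_seq
    qry = encode(query_seq) if isinstance(query_seq, str) else query_seq
    ref_limits = _midpoint_limits([(m.ref_start, m.ref_end) for m in mems], rep.size)
    qry_limits = _midpoint_limits([(m.query_start, m.query_end) for m in mems], qry.size)
    out: list[ExtendedMatch] = []
    for m, (rl, rr), (ql, qr) in zip(mems, ref_limits, qry_limits):
        # leftward: windows reversed so index 0 is the first consumed char
        li, lj, ln = _extend_one_side(
            rep[m.ref_start - rl : m.ref_start][::-1].copy(),
            qry[m.query_start - ql : m.query_start][::-1].copy(),
            scheme,
        )
        ri, rj, rn = _extend_one_side(
            rep[m.ref_end : m.ref_end + rr].copy(),
            qry[m.query_end : m.query_end + qr].copy(),
            scheme,
        )
        out.append(
            ExtendedMatch(
                source=m,
                ext_ref_span=(m.ref_start - li, m.ref_end + ri),
                ext_query_span=(m.query_start - lj, m.query_end + rj),
                n_match=m.length + ln + rn,
            )
        )
    return out


def compute_ememi(ext: list[ExtendedMatch], l_query: int) -> IdentityResult:
    """eMEMi = min(1, sum of matched bases / query length)."""
    if l_query < 1:
        raise ValueError(f"l_query must be >= 1, got {l_query}")
    total = sum(e.n_match for e in ext)
    strand = ext[0].source.strand if ext else "+"
    return IdentityResult(min(1.0, total / l_query), total, l_query, strand)


def refine_and_extend(
    mems: list[MEM],
    rep_seq: str | np.ndarray,
    query_seq: str | np.ndarray,
    scheme: ScoreScheme | None = None,
) -> list[ExtendedMatch]:
    """Full refinement pipeline: containment removal, trimming, extension."""
    return extend_matches(trim_overlaps(remove_contained(mems)), rep_seq, query_seq, scheme)
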