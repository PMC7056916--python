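"""Enumeration of maximal exact matches (MEMs) against a suffix index.

A MEM is an exact match between a query and an indexed sequence that cannot
be extended on either side without a mismatch, an ``N``, or a sequence
boundary.  Only MEMs of length >= L are reported; with a sparse step K the
index stores every K-th suffix, so the search matches query windows of
length tau = L - K + 1 and verifies left-maximality by scanning at most
K - 1 characters — every MEM of length >= L >= K contains exactly one
*first* sampled reference position, from which it is emitted exactly once.
The reported MEM set is therefore independent of K whenever L >= K.

Minus-strand MEMs are found against the reverse-complemented query and
reported in forward-query coordinates:
``query_start = |query| - (rc_start + length)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .io_fasta import SequenceRecord, reverse_complement
from .suffix_index import SuffixIndex, encode

__all__ = ["MEM", "find_mems", "collect_mems_filtered", "brute_force_mems"]


@dataclass(frozen=True, order=True)
class MEM:
    """One maximal exact match, in forward-query coordinates."""

    ref_id: str
    ref_start: int
    query_start: int
    length: int
    strand: str = "+"

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def query_end(self) -> int:
        return self.query_start + self.length


def _scan(index: SuffixIndex, query_arr: np.ndarray, L: int, min_member_length: int):
    cap = 4096
    while True:
        out = np.empty((cap, 4), dtype=np.int64)
        n = _kernels.mem_scan(
            index.text,
            index.SA,
            index._pos_member,
            index.boundaries,
            index.member_lengths,
            index.K,
            L,
            query_arr,
            min_member_length,
            out,
        )
        if n <= cap:
            return out[:n]
        cap = max(cap * 2, n)


def find_mems(
    index: SuffixIndex,
    query: SequenceRecord | str,
    L: int,
    both_strands: bool = False,
    min_member_length: int = 0,
) -> list[MEM]:
    """All MEMs of length >= ``L`` between ``query`` and the indexed members.

    ``min_member_length`` drops, during collection, every MEM lying on an
    indexed member shorter than that many bp (0 disables the filter).
    Results are sorted by (ref member, strand, ref_start, query_start) and
    contain no duplicates.
    """
    if L < 1:
        raise ValueError(f"minimum MEM length L must be >= 1, got {L}")
    if L < index.K:
        raise ValueError(
            f"L={L} is below the sparse step K={index.K}: a match shorter "
            f"than the sampling step cannot be anchored on a sampled suffix; "
            f"use L >= K (or rebuild the index with a smaller K)"
        )
    seq = query.seq if isinstance(query, SequenceRecord) else query
    ids = index.member_ids
    mems: list[MEM] = []
    rows = _scan(index, encode(seq), L, min_member_length)
    for mem_i, rstart, qstart, length in rows:
        mems.append(MEM(ids[mem_i], int(rstart), int(qstart), int(length), "+"))
    if both_strands:
        m = len(seq)
        rows = _scan(index, encode(reverse_complement(seq)), L, min_member_length)
        for mem_i, rstart, rc_qstart, length in rows:
            qstart = m - (int(rc_qstart) + int(length))
            mems.append(MEM(ids[mem_i], int(rstart), qstart, int(length), "-"))
    mems.sort(key=lambda x: (x.ref_id, x.strand, x.ref_start, x.query_start))
    return mems


def collect_mems_filtered(
    index: SuffixIndex,
    query: SequenceRecord | str,
    L: int,
    min_member_length: int,
    both_strands: bool = False,
) -> list[MEM]:
    """:func:`find_mems` with MEMs on members shorter than ``min_member_length``
    discarded at collection time (they are never materialized)."""
    return find_mems(index, query, L, both_strands, min_member_length)


def brute_force_mems(ref: str, query: str, L: int) -> set[tuple[int, int, int]]:
    """Definitionally complete quadratic MEM enumeration (oracle).

    Scans every diagonal of the (ref, query) match matrix for maximal runs
    of matching non-N characters and returns {(ref_start, query_start,
    length)} for runs of length >= L.  Intended for |ref|*|query| up to a
    ~10^6-cell budget.
    """
    if L < 1:
        raise ValueError(f"minimum MEM length L must be >= 1, got {L}")
    a = encode(ref)
    b = encode(query)
    cap = 4096
    while True:
        out = np.empty((cap, 3), dtype=np.int64)
        n = _kernels.brute_mems(a, b, L, out)
        if n <= cap:
            return {(int(r), int(q), int(l)) for r, q, l in out[:n]}
        cap = max(cap * 2, n)
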