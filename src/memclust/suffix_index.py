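"""Sparse suffix array + LCP index over a concatenation of sequences.

The text is the integer-encoded concatenation of the member sequences, each
followed by a terminator.  Nucleotides map to small positive codes in ASCII
order (A=1 < C=2 < G=3 < N=4 < T=5); the terminator after member *i* gets the
negative code ``-(i+1)``.  Terminators therefore compare below every
nucleotide and are pairwise distinct, so no suffix comparison — during
construction, LCP computation or search — can ever run across a sequence
boundary, and all suffixes of the text are distinct.

The suffix array is *sparse*: only suffixes starting at text positions
``p ≡ 0 (mod K)`` are stored (terminator positions are skipped — such a
suffix can never match a pattern).  ``K = 1`` gives the full suffix array.
Sorting uses prefix-doubling on numpy integer ranks, which is deterministic
and close to ``O(n log n)`` at the scales this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .io_fasta import SequenceRecord

__all__ = ["SuffixIndex", "MatchInterval", "build_index", "encode", "decode"]

_ENCODE_TABLE = np.zeros(256, dtype=np.int32)
for _i, _c in enumerate("ACGNT", start=1):
    _ENCODE_TABLE[ord(_c)] = _i
_DECODE = {i: c for i, c in enumerate("ACGNT", start=1)}


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string into int32 codes (A=1,C=2,G=3,N=4,T=5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENCODE_TABLE[raw]
    if seq and out.min() == 0:
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    return out


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[int(v)] for v in arr)


def _suffix_sort(text: np.ndarray) -> np.ndarray:
    """Full suffix array of an integer text by prefix doubling.

    All suffixes are distinct (distinct terminators), so the doubling loop
    always terminates with a total order.
    """
    n = text.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(text, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord = rank[order]
        k_ord = key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


@dataclass(frozen=True)
class MatchInterval:
    """Result of a longest-prefix search against the sampled suffix array.

    ``d_start..d_end`` (inclusive) is the SA interval of sampled suffixes
    matching the pattern to at least the search threshold; ``q_start..q_end``
    is its subinterval achieving the longest match, of length ``match_len``.
    An empty sentinel has ``d_end < d_start``.
    """

    d_start: int
    d_end: int
    q_start: int
    q_end: int
    match_len: int

    @property
    def is_empty(self) -> bool:
        return self.d_end < self.d_start


EMPTY_INTERVAL = MatchInterval(0, -1, 0, -1, 0)


class SuffixIndex:
    """Sparse suffix array over the concatenation of representative sequences."""

    def __init__(self, records: Sequence[SequenceRecord], K: int):
        if K < 1:
            raise ValueError(f"sparse step K must be >= 1, got {K}")
        if not records:
            raise ValueError("cannot build an index over zero sequences")
        self.K = int(K)
        self.members: list[tuple[str, int]] = [(r.id, r.length) for r in records]
        n_members = len(records)
        total = sum(r.length for r in records) + n_members
        text = np.empty(total, dtype=np.int32)
        pos_member = np.full(total, -1, dtype=np.int32)
        boundaries = np.empty(n_members, dtype=np.int64)
        member_len = np.empty(n_members, dtype=np.int64)
        off = 0
        for i, rec in enumerate(records):
            boundaries[i] = off
            member_len[i] = rec.length
            text[off : off + rec.length] = encode(rec.seq)
            pos_member[off : off + rec.length] = i
            off += rec.length
            text[off] = -(i + 1)  # distinct terminator, below all nucleotides
            off += 1
        self.text = text
        self.boundaries = boundaries
        self.member_lengths = member_len
        self._pos_member = pos_member
        full = _suffix_sort(text)
        keep = (full % self.K == 0) & (text[full] > 0)
        self.SA = full[keep]
        self.LCP = _kernels.adjacent_lcp(text, self.SA)

    # -- queries ---------------------------------------------------------

    def locate(self, text_pos: int) -> tuple[str, int]:
        """Map a text position to (sequence_id, 0-based offset in sequence)."""
        if not 0 <= text_pos < self.text.size:
            raise IndexError(f"text position {text_pos} out of range")
        i = int(np.searchsorted(self.boundaries, text_pos, side="right")) - 1
        offset = text_pos - int(self.boundaries[i])
        if offset >= self.members[i][1]:
            raise ValueError(f"text position {text_pos} is a terminator")
        return self.members[i][0], offset

    def search_longest(self, pattern: str, min_len: int = 1) -> MatchInterval:
        """Longest-prefix match of ``pattern`` against the sampled suffixes.

        ``N`` in the pattern matches nothing, so the effective pattern ends
        at its first ``N``.  Returns the empty sentinel when no sampled
        suffix shares even one leading character.
        """
        pat = encode(pattern)
        n_idx = int(np.argmax(pat == _kernels.N_CODE))
        if pat.size and pat[n_idx] == _kernels.N_CODE:
            pat = pat[:n_idx]
        if pat.size == 0:
            return EMPTY_INTERVAL
        text, sa = self.text, self.SA
        lo, hi = _kernels.window_bounds(text, sa, pat, 0, pat.size)
        best = 0
        for nb in (lo - 1, lo if lo < sa.size else -1):
            if 0 <= nb < sa.size:
                best = max(best, _kernels.match_len(text, sa[nb], pat, 0))
        if hi > lo:  # full pattern present
            best = pat.size
        if best == 0:
            return EMPTY_INTERVAL
        q_lo, q_hi = _kernels.window_bounds(text, sa, pat, 0, best)
        if best >= min_len:
            d_lo, d_hi = _kernels.window_bounds(text, sa, pat, 0, min(min_len, best))
        else:
            d_lo, d_hi = q_lo, q_hi
        return MatchInterval(d_lo, d_hi - 1, q_lo, q_hi - 1, best)

    @property
    def member_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SuffixIndex(members={len(self.members)}, "
            f"text={self.text.size}, K={self.K}, sampled={self.SA.size})"
        )


def build_index(records: Sequence[SequenceRecord], K: int = 1) -> SuffixIndex:
    """Build a :class:`SuffixIndex` over ``records`` with sparse step ``K``."""
    return SuffixIndex(records, K)
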