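"""Greedy incremental, block-partitioned clustering of length-sorted sequences.

The input (already filtered and sorted long-to-short) is split into blocks
whose total sequence fits a memory budget.  Within a block, each sequence is
compared — via MEM enumeration, refinement and eMEMi — against the block's
representatives discovered so far: the first representative (in discovery
order) whose best-strand identity meets the threshold absorbs it, otherwise
the sequence founds a new cluster.  After a block is finished, every
not-yet-assigned sequence in later blocks is screened against the block's
representative index; over the main loop each sequence is therefore
eventually compared against every earlier representative.

Screening queries against a fixed index are independent of each other, so
they may be distributed over threads; assignments are applied in global
rank order afterwards, which makes the result identical for every thread
count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from .io_fasta import SequenceRecord, reverse_complement
from .mem_finder import MEM
from .mem_refine import ScoreScheme, compute_ememi, refine_and_extend
from .suffix_index import SuffixIndex, encode

__all__ = [
    "ClusteringParams",
    "Cluster",
    "ClusterSet",
    "partition_blocks",
    "assign_or_promote",
    "cluster_block",
    "cluster_all",
    "RepresentativeSet",
]

logger = logging.getLogger(__name__)

#: slack for the identity-threshold comparison (floating-point only; eMEMi
#: itself is a ratio of integers)
_EPS = 1e-9


@dataclass(frozen=True)
class ClusteringParams:
    """Knobs of the clustering run.

    minlen
        Minimum MEM length L in bp (default 21: under a uniform random
        model no chance maximal match materially longer than that is
        expected between Mbp-scale genomes).
    memiden
        Identity threshold in percent of eMEMi (default 90).
    sparse_k
        Sparse suffix-array step K (default 1; 2-4 trade index size for a
        requirement that minlen >= K).
    chunk_mb
        Block size budget in Mbp of representative text (default 400).
    rebuild
        Fold newly promoted representatives into the block's main index
        every ``rebuild_interval`` promotions; when off, recent
        representatives are only searched through small per-sequence
        indexes within their block.
    """

    minlen: int = 21
    memiden: float = 90.0
    sparse_k: int = 1
    chunk_mb: float = 400.0
    both_strands: bool = False
    gapped: bool = False
    rebuild: bool = True
    rebuild_interval: int = 64
    threads: int = 1
    scheme: ScoreScheme = field(default_factory=ScoreScheme)

    def __post_init__(self) -> None:
        if not 0 < self.memiden <= 100:
            raise ValueError(f"memiden must be in (0, 100], got {self.memiden}")
        if self.minlen < 1:
            raise ValueError(f"minlen must be >= 1, got {self.minlen}")
        if self.sparse_k < 1:
            raise ValueError(f"sparse_k must be >= 1, got {self.sparse_k}")
        if self.minlen < self.sparse_k:
            raise ValueError(
                f"minlen ({self.minlen}) must be >= sparse_k ({self.sparse_k})"
            )
        if self.chunk_mb <= 0:
            raise ValueError(f"chunk_mb must be > 0, got {self.chunk_mb}")
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")
        if self.rebuild_interval < 1:
            raise ValueError("rebuild_interval must be >= 1")
        if self.scheme.gapped != self.gapped:
            object.__setattr__(self, "scheme", replace(self.scheme, gapped=self.gapped))


@dataclass(frozen=True)
class Cluster:
    """One cluster: its representative and the (member, identity, strand) list."""

    representative: str
    members: tuple[tuple[str, float, str], ...]

    @property
    def size(self) -> int:
        return 1 + len(self.members)


@dataclass(frozen=True)
class ClusterSet:
    """Partition of the input into clusters, one representative each."""

    clusters: tuple[Cluster, ...]
    params: ClusteringParams
    records: tuple[SequenceRecord, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        """Map every sequence id to its cluster's representative id."""
        out: dict[str, str] = {}
        for c in self.clusters:
            out[c.representative] = c.representative
            for member_id, _, _ in c.members:
                out[member_id] = c.representative
        return out


def partition_blocks(
    records: list[SequenceRecord], chunk_mb: float
) -> list[list[SequenceRecord]]:
    """Greedy fill of length-sorted records into blocks of <= chunk_mb Mbp.

    A single record larger than the budget gets a block of its own.
    """
    budget = chunk_mb * 1e6
    blocks: list[list[SequenceRecord]] = []
    current: list[SequenceRecord] = []
    total = 0
    for rec in records:
        if current and total + rec.length > budget:
            blocks.append(current)
            current = []
            total = 0
        current.append(rec)
        total += rec.length
    if current:
        blocks.append(current)
    return blocks


class _Query:
    """A query sequence with cached encodings for both strands."""

    __slots__ = ("record", "fwd", "rc")

    def __init__(self, record: SequenceRecord, both: bool):
        self.record = record
        self.fwd = encode(record.seq)
        self.rc = encode(reverse_complement(record.seq)) if both else None


class RepresentativeSet:
    """Representatives discovered so far, searchable as one unit.

    Holds a main suffix index over the representatives indexed so far plus
    small per-sequence indexes for representatives promoted since the last
    rebuild; queries are searched against both, so results never depend on
    the rebuild schedule.
    """

    def __init__(self, params: ClusteringParams):
        self.params = params
        self.records: list[SequenceRecord] = []
        self._main_index: SuffixIndex | None = None
        self._indexed_upto = 0
        self._buffer_indexes: list[SuffixIndex] = []
        self._encoded: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: SequenceRecord) -> None:
        self.records.append(record)
        self._encoded[record.id] = encode(record.seq)
        self._buffer_indexes.append(SuffixIndex([record], self.params.sparse_k))
        if (
            self.params.rebuild
            and len(self.records) - self._indexed_upto >= self.params.rebuild_interval
        ):
            self.rebuild()

    def rebuild(self) -> None:
        """Rebuild the main index from scratch over all representatives."""
        if not self.records:
            return
        self._main_index = SuffixIndex(self.records, self.params.sparse_k)
        self._indexed_upto = len(self.records)
        self._buffer_indexes = []

    def match(self, query: _Query | SequenceRecord) -> tuple[str, float, str] | None:
        """First representative (discovery order) meeting the identity threshold.

        Returns (representative_id, identity fraction, strand) or None.  The
        minus strand is evaluated against the reverse-complemented query in
        its own frame; the better strand wins per representative, and
        strands are never pooled into one matched-base sum.
        """
        p = self.params
        if isinstance(query, SequenceRecord):
            query = _Query(query, p.both_strands)
        groups = self._raw_groups(query)
        if not groups:
            return None
        l_query = query.record.length
        for rec in self.records:
            best: tuple[float, str] | None = None
            for strand in ("+", "-"):
                # minus-strand MEMs stay in the reverse-complemented query
                # frame: that is where the match content is collinear
                mems = groups.get((rec.id, strand))
                if not mems:
                    continue
                qarr = query.fwd if strand == "+" else query.rc
                if strand == "-":
                    mems = [replace(m, strand="-") for m in mems]
                ext = refine_and_extend(mems, self._encoded[rec.id], qarr, p.scheme)
                res = compute_ememi(ext, l_query)
                if best is None or res.ememi > best[0]:
                    best = (res.ememi, strand)
            if best is not None and best[0] * 100.0 >= p.memiden - _EPS:
                return rec.id, best[0], best[1]
        return None

    def _raw_groups(self, query: _Query) -> dict[tuple[str, str], list[MEM]]:
        p = self.params
        min_len = query.record.length
        groups: dict[tuple[str, str], list[MEM]] = {}
        indexes = ([self._main_index] if self._main_index is not None else []) + \
            self._buffer_indexes
        for idx in indexes:
            for strand, arr in (("+", query.fwd), ("-", query.rc)):
                if arr is None:
                    continue
                rows = _scan_encoded(idx, arr, p.minlen, min_len)
                for m in rows:
                    groups.setdefault((m.ref_id, strand), []).append(m)
        return groups


def _scan_encoded(index: SuffixIndex, arr: np.ndarray, L: int, min_member_length: int):
    """collect_mems_filtered on an already-encoded query array.

    Minus-strand callers pass the reverse-complement encoding; MEMs come
    back in that array's own coordinate frame.
    """
    from .mem_finder import _scan

    if L < index.K:
        raise ValueError(f"L={L} below sparse step K={index.K}")
    ids = index.member_ids
    rows = _scan(index, arr, L, min_member_length)
    return [
        MEM(ids[mi], int(rs), int(qs), int(ln), "+") for mi, rs, qs, ln in rows
    ]


def assign_or_promote(
    query: SequenceRecord, representatives: RepresentativeSet, params: ClusteringParams
) -> tuple[str, tuple[str, float, str] | None]:
    """Classify ``query`` against ``representatives``.

    Returns ``("redundant", (rep_id, identity, strand))`` when the first
    representative in discovery order reaches the identity threshold, else
    ``("representative", None)`` after promoting the query.
    """
    hit = representatives.match(query)
    if hit is not None:
        return "redundant", hit
    representatives.add(query)
    return "representative", None


def cluster_block(
    block: list[SequenceRecord],
    carried_representatives: RepresentativeSet | None,
    params: ClusteringParams,
    preassigned: dict[str, tuple[str, float, str]] | None = None,
) -> tuple[dict[str, tuple[str, float, str]], RepresentativeSet]:
    """Intra-block pass: sequentially classify each sequence in the block.

    ``carried_representatives`` (from earlier blocks) are consulted first
    when given; sequences already in ``preassigned`` are skipped.  Returns
    the block's assignments and its representative set.
    """
    assignments: dict[str, tuple[str, float, str]] = {}
    repset = RepresentativeSet(params)
    for rec in block:
        if preassigned and rec.id in preassigned:
            continue
        if carried_representatives is not None and len(carried_representatives):
            hit = carried_representatives.match(rec)
            if hit is not None:
                assignments[rec.id] = hit
                logger.debug("%s -> redundant vs carried %s", rec.id, hit[0])
                continue
        status, hit = assign_or_promote(rec, repset, params)
        if status == "redundant":
            assignments[rec.id] = hit
            logger.debug("%s -> redundant vs %s (%.4f, %s)", rec.id, *hit)
        else:
            logger.debug("%s -> new representative", rec.id)
    return assignments, repset


def _screen(
    queries: list[SequenceRecord], repset: RepresentativeSet, params: ClusteringParams
) -> dict[str, tuple[str, float, str]]:
    """Inter-block screening of independent queries against a fixed index."""
    both = params.both_strands
    if params.threads <= 1 or len(queries) < 2:
        results = [repset.match(_Query(q, both)) for q in queries]
    else:
        with ThreadPoolExecutor(max_workers=params.threads) as pool:
            results = list(pool.map(lambda q: repset.match(_Query(q, both)), queries))
    return {q.id: hit for q, hit in zip(queries, results) if hit is not None}


def cluster_all(
    records: list[SequenceRecord], params: ClusteringParams | None = None
) -> ClusterSet:
    """Cluster filtered, length-sorted records into a :class:`ClusterSet`.

    The result is deterministic and identical for every thread count and
    for every block partition of the same input.
    """
    if params is None:
        params = ClusteringParams()
    for a, b in zip(records, records[1:]):
        if a.length < b.length:
            raise ValueError("records must be sorted long-to-short (see filter_and_sort)")
    blocks = partition_blocks(records, params.chunk_mb)
    assigned: dict[str, tuple[str, float, str]] = {}
    rep_order: list[str] = []
    for bi, block in enumerate(blocks):
        block_assignments, repset = cluster_block(block, None, params, assigned)
        assigned.update(block_assignments)
        rep_order.extend(r.id for r in repset.records)
        later = [
            rec
            for later_block in blocks[bi + 1 :]
            for rec in later_block
            if rec.id not in assigned
        ]
        if later and len(repset):
            repset.rebuild()  # one consolidated index for the screening pass
            assigned.update(_screen(later, repset, params))
        logger.info(
            "block %d/%d: %d sequences, %d representatives so far",
            bi + 1,
            len(blocks),
            len(block),
            len(rep_order),
        )
    members: dict[str, list[tuple[str, float, str]]] = {r: [] for r in rep_order}
    rank = {rec.id: i for i, rec in enumerate(records)}
    for seq_id, (rep_id, identity, strand) in assigned.items():
        members[rep_id].append((seq_id, identity, strand))
    clusters = tuple(
        Cluster(rep_id, tuple(sorted(members[rep_id], key=lambda t: rank[t[0]])))
        for rep_id in rep_order
    )
    return ClusterSet(clusters, params, tuple(records))
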