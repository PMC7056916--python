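"""FASTA input, sequence sanitization, length sorting and cluster output.

Sequences are nucleotide-only.  On input, lowercase letters are uppercased,
``U`` is read as ``T`` and every IUPAC ambiguity code other than ``N``
(R, Y, S, W, K, M, B, D, H, V) collapses to ``N``: the match alphabet must
stay small and ``N`` never matches anything downstream, so finer ambiguity
information cannot influence clustering anyway.

Cluster membership is written in the CD-HIT ``.clstr`` dialect for
interoperability with existing dereplication tooling, alongside a FASTA of
representatives and a flat TSV summary.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .cluster_engine import ClusterSet

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "read_fasta",
    "filter_and_sort",
    "reverse_complement",
    "write_cluster_output",
    "write_summary",
    "parse_clstr",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA records (empty header or sequence)."""


_AMBIGUOUS = "RYSWKMBDHV"
_SANITIZE = str.maketrans(
    "acgtun" + _AMBIGUOUS.lower() + "U" + _AMBIGUOUS,
    "ACGTTN" + "N" * len(_AMBIGUOUS) + "T" + "N" * len(_AMBIGUOUS),
)
_VALID = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence with its 0-based input rank."""

    id: str
    seq: str
    input_rank: int

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not _VALID.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(
                f"record {self.id!r}: sequence contains characters outside "
                f"A/C/G/T/N after sanitization: {bad}"
            )


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def sanitize(seq: str, record_index: int | None = None, record_id: str = "") -> str:
    """Uppercase and collapse ambiguity codes; reject non-nucleotide characters."""
    out = seq.upper().translate(_SANITIZE)
    if not _VALID.match(out):
        bad = sorted(set(out) - set("ACGTN"))
        where = f" (record {record_index}, id {record_id!r})" if record_index is not None else ""
        raise FastaParseError(f"invalid sequence characters {bad}{where}")
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into sanitized records.

    Records keep file order; ``input_rank`` is their 0-based position.
    Empty headers or empty sequences raise :class:`FastaParseError` naming
    the offending record index.
    """
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            if not rec.id:
                raise FastaParseError(f"record {i}: empty FASTA header")
            seq = str(rec.seq)
            if not seq:
                raise FastaParseError(f"record {i} ({rec.id!r}): empty sequence")
            records.append(SequenceRecord(rec.id, sanitize(seq, i, rec.id), i))
    return records


def filter_and_sort(records: Iterable[SequenceRecord], min_keep: int) -> list[SequenceRecord]:
    """Drop sequences shorter than ``min_keep`` bp and sort long-to-short.

    Ties in length are broken by ascending input rank (stable), which makes
    greedy clustering deterministic.  Idempotent.
    """
    if min_keep < 1:
        raise ValueError(f"min_keep must be >= 1, got {min_keep}")
    kept = [r for r in records if r.length >= min_keep]
    kept.sort(key=lambda r: (-r.length, r.input_rank))
    return kept


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N is a fixed point."""
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_cluster_output(clusters: "ClusterSet", out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.rep.fasta`` and ``<prefix>.clstr``.

    The ``.clstr`` file is CD-HIT style: one ``>Cluster n`` header per
    cluster, then one indented line per member carrying its length, id and
    either ``*`` (the representative) or ``at <strand>/<identity>%``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta_path = out_prefix.with_suffix(out_prefix.suffix + ".rep.fasta")
    clstr_path = out_prefix.with_suffix(out_prefix.suffix + ".clstr")
    seq_of = {r.id: r for r in clusters.records}
    with open(fasta_path, "w") as fa, open(clstr_path, "w") as cl:
        for n, cluster in enumerate(clusters.clusters):
            rep = seq_of[cluster.representative]
            fa.write(f">{rep.id}\n{_wrap(rep.seq)}\n")
            cl.write(f">Cluster {n}\n")
            cl.write(f"0\t{rep.length}nt, >{rep.id}... *\n")
            for k, (member_id, identity, strand) in enumerate(cluster.members, start=1):
                length = seq_of[member_id].length
                cl.write(
                    f"{k}\t{length}nt, >{member_id}... at {strand}/{identity * 100:.2f}%\n"
                )
    return fasta_path, clstr_path


def write_summary(clusters: "ClusterSet", path: str | Path) -> Path:
    """Tab-separated summary: cluster_id, representative, member, identity%, strand."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tidentity_pct\tstrand\n")
        for n, cluster in enumerate(clusters.clusters):
            fh.write(f"{n}\t{cluster.representative}\t{cluster.representative}\t100.00\t+\n")
            for member_id, identity, strand in cluster.members:
                fh.write(
                    f"{n}\t{cluster.representative}\t{member_id}\t"
                    f"{identity * 100:.2f}\t{strand}\n"
                )
    return path


_CLSTR_MEMBER = re.compile(
    r"^(\d+)\t(\d+)nt, >(.*)\.\.\. (?:\*|at ([+-])/([0-9.]+)%)$"
)


def parse_clstr(path: str | Path) -> dict[str, list[tuple[str, float | None, str | None]]]:
    """Parse a ``.clstr`` file back into {representative: [(member, identity, strand)]}.

    The representative itself appears with identity ``None``.  Used for
    round-trip checking of :func:`write_cluster_output`.
    """
    result: dict[str, list[tuple[str, float | None, str | None]]] = {}
    current: list[tuple[str, float | None, str | None]] = []
    rep: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                if rep is not None:
                    result[rep] = current
                rep = None
                current = []
                continue
            m = _CLSTR_MEMBER.match(line)
            if not m:
                raise ValueError(f"unparseable .clstr line: {line!r}")
            member = m.group(3)
            if m.group(4) is None:
                rep = member
                current.insert(0, (member, None, None))
            else:
                current.append((member, float(m.group(5)) / 100.0, m.group(4)))
    if rep is not None:
        result[rep] = current
    return result
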