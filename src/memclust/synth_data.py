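"""Deterministic synthetic genome collections with known redundancy structure.

Every sequence is i.i.d. uniform over {A, C, G, T} (the null model under
which a 21-bp minimum MEM length suppresses chance matches), so unrelated
sequences share essentially no long exact match.  Redundant groups are
planted by copying a representative — optionally truncated — and mutating it
with point substitutions and short (1-3 bp) indels to a target identity.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_fasta import SequenceRecord

__all__ = ["BenchmarkTruth", "random_genome", "mutate_genome", "make_benchmark"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BenchmarkTruth:
    """Synthetic dataset plus its planted partition."""

    records: tuple[SequenceRecord, ...]
    truth: dict[str, str]  # sequence_id -> group_id
    planted_identity: dict[str, float]  # derived sequences only

    @property
    def n_groups(self) -> int:
        return len(set(self.truth.values()))


def random_genome(length: int, seed: int | np.random.Generator) -> str:
    """Uniform-random nucleotide string, identical for identical (length, seed)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_genome(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> tuple[str, float]:
    """Mutate ``seq`` with per-position substitutions and short indels.

    Each position substitutes to a different base with probability
    ``sub_rate``; independently, with probability ``indel_rate`` an indel of
    length 1-3 is placed there (deletion removes the following bases,
    insertion adds random ones).  Returns the mutated string and a realized
    identity estimate: matched positions divided by the shorter of the two
    lengths, assuming indels shift rather than destroy the alignment.
    """
    if not (0 <= sub_rate < 0.5 and 0 <= indel_rate < 0.5):
        raise ValueError("mutation rates must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    sub_mask = rng.random(n) < sub_rate
    sub_mask &= arr != ord("N")  # unknown bases stay unknown
    n_sub = int(sub_mask.sum())
    if n_sub:
        # shift within {A,C,G,T} by 1-3 so the base always changes
        code = np.searchsorted(_BASES, arr[sub_mask])
        arr[sub_mask] = _BASES[(code + rng.integers(1, 4, size=n_sub)) % 4]
    n_del = 0
    if indel_rate > 0:
        pieces: list[np.ndarray] = []
        pos = 0
        events = np.flatnonzero(rng.random(n) < indel_rate)
        for ev in events:
            if ev < pos:
                continue  # swallowed by a previous deletion
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pieces.append(arr[pos:ev])
                pos = min(ev + size, n)
                n_del += pos - ev
            else:  # insertion
                pieces.append(arr[pos : ev + 1])
                pieces.append(_BASES[rng.integers(0, 4, size=size)])
                pos = ev + 1
        pieces.append(arr[pos:])
        arr = np.concatenate(pieces) if len(pieces) > 1 else pieces[0]
    mutated = arr.tobytes().decode("ascii")
    matched = n - n_sub - n_del
    shorter = min(n, len(mutated))
    identity = max(0.0, min(1.0, matched / shorter)) if shorter else 0.0
    return mutated, identity


def make_benchmark(
    n_groups: int = 20,
    copies_per_group: int = 3,
    rep_length_range: tuple[int, int] = (2000, 4000),
    identity_target: float = 0.95,
    n_singletons: int = 30,
    seed: int = 0,
    indel_share: float = 0.0,
    truncate_range: tuple[float, float] = (0.75, 0.95),
    singleton_length_range: tuple[int, int] = (500, 2000),
    out_fasta: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> BenchmarkTruth:
    """Build a benchmark of planted redundant groups plus unrelated singletons.

    Each group has one uniform-random representative and ``copies_per_group``
    derived copies: a truncated prefix (fraction drawn from
    ``truncate_range``, so every copy is strictly shorter than its
    representative) mutated to approximately ``identity_target``.
    ``indel_share`` is the fraction of the mutation budget spent on short
    indels instead of substitutions (0 = substitutions only).  Identity 1.0
    yields exact prefix copies.

    Optionally writes the FASTA and a tab-separated truth table
    (sequence_id, group_id, planted_identity).
    """
    if not 0.5 < identity_target <= 1.0:
        raise ValueError("identity_target must lie in (0.5, 1]")
    if not 0 <= indel_share <= 1:
        raise ValueError("indel_share must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mut_budget = 1.0 - identity_target
    sub_rate = mut_budget * (1.0 - indel_share)
    indel_rate = mut_budget * indel_share / 2.0  # mean indel length 2
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    planted: dict[str, float] = {}
    rank = 0
    for g in range(n_groups):
        group = f"group{g}"
        length = int(rng.integers(rep_length_range[0], rep_length_range[1] + 1))
        rep_seq = random_genome(length, rng)
        rep_id = f"{group}_rep"
        records.append(SequenceRecord(rep_id, rep_seq, rank))
        truth[rep_id] = group
        rank += 1
        for c in range(copies_per_group):
            frac = rng.uniform(*truncate_range)
            prefix = rep_seq[: max(1, int(length * frac))]
            copy_seq, realized = mutate_genome(prefix, sub_rate, indel_rate, rng)
            copy_id = f"{group}_copy{c}"
            records.append(SequenceRecord(copy_id, copy_seq, rank))
            truth[copy_id] = group
            planted[copy_id] = realized
            rank += 1
    for s in range(n_singletons):
        length = int(rng.integers(singleton_length_range[0], singleton_length_range[1] + 1))
        sid = f"singleton{s}"
        records.append(SequenceRecord(sid, random_genome(length, rng), rank))
        truth[sid] = sid
        rank += 1
    bench = BenchmarkTruth(tuple(records), truth, planted)
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n")
                for i in range(0, rec.length, 70):
                    fh.write(rec.seq[i : i + 70] + "\n")
    if out_truth is not None:
        with open(out_truth, "w") as fh:
            fh.write("sequence_id\tgroup_id\tplanted_identity\n")
            for rec in records:
                ident = planted.get(rec.id)
                fh.write(
                    f"{rec.id}\t{truth[rec.id]}\t"
                    f"{'' if ident is None else f'{ident:.4f}'}\n"
                )
    return bench
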