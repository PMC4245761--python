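"""Exact k-mer counting and per-read median k-mer frequency (RMKF).

Counting is exact (a hash table over k-mer strings), non-canonical —
forward and reverse-complement k-mers are kept as distinct keys — and
skips any window containing an ambiguous base.  The RMKF of a read is the
median of its valid k-mers' dataset-wide counts; for even-length count
lists the LOWER median is taken, keeping the statistic integer-valued and
deterministic.  RMKF tracks a read's true sequencing depth closely enough
to drive reference-free normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from kmernorm.io import ReadSet, SequenceRecord

DEFAULT_K = 19

_ACGT = frozenset("ACGT")


@dataclass
class KmerCountTable:
    """Exact counts of all length-``k`` ACGT words over the input's forward
    sequences.  Keys never contain N; strands are never merged."""

    k: int = DEFAULT_K
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "KmerCountTable":
        """Load a user-supplied count table (standalone mode)."""
        k = None
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#k="):
                        k = int(line[3:])
                    continue
                kmer, n = line.split("\t")
                counts[kmer] = int(n)
        if k is None:
            if not counts:
                raise ValueError(f"{path}: empty k-mer table with no #k= header")
            k = len(next(iter(counts)))
        for kmer in counts:
            if len(kmer) != k or set(kmer) - _ACGT:
                raise ValueError(f"{path}: bad k-mer key {kmer!r} for k={k}")
        return cls(k=k, counts=counts)


def _valid_kmers(bases: str, k: int) -> Iterable[str]:
    """All length-k windows of ``bases`` that contain no N.

    Scans the maximal N-free runs so N-adjacent windows are skipped without
    per-window membership tests.
    """
    start = 0
    n = len(bases)
    while start < n:
        stop = bases.find("N", start)
        if stop == -1:
            stop = n
        for i in range(start, stop - k + 1):
            yield bases[i : i + k]
        start = stop + 1


def count_kmers(
    reads: Union[ReadSet, Iterable[Union[SequenceRecord, str]]],
    k: int = DEFAULT_K,
) -> KmerCountTable:
    """Tally every valid k-mer across all reads' forward sequences."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: dict[str, int] = {}
    longest = 0
    for read in reads:
        bases = read if isinstance(read, str) else read.bases
        longest = max(longest, len(bases))
        for kmer in _valid_kmers(bases, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    if longest and not counts and k > longest:
        warnings.warn(
            f"k={k} exceeds the longest read ({longest} bp); "
            "k-mer table is empty",
            stacklevel=2,
        )
    return KmerCountTable(k=k, counts=counts)


def lower_median(values: list[int]) -> int:
    """Median with the lower of the two middle elements on even length."""
    if not values:
        return 0
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def read_rmkf(
    record: Union[SequenceRecord, str], table: KmerCountTable
) -> int:
    """Median dataset-wide frequency of the read's valid k-mers.

    Reads contributing no valid k-mer get RMKF 0 (and are later removed by
    the input filter).  K-mers absent from the table — possible only with a
    user-supplied table — count as 0.
    """
    bases = record if isinstance(record, str) else record.bases
    freqs = [table.get(kmer) for kmer in _valid_kmers(bases, table.k)]
    return lower_median(freqs)


def rmkf_profile(readset: ReadSet, table: KmerCountTable) -> dict[str, int]:
    """RMKF for every read in the set, keyed by read id."""
    return {rec.read_id: read_rmkf(rec, table) for rec in readset}
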