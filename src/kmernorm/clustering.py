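"""Greedy incremental sequence clustering within a retention bin.

Targeted selection ranks sub-bin clusters by uniqueness, so each bin is
clustered with cd-hit-est-style greedy rules: reads are visited longest
first; a read joins the first existing cluster whose representative it
matches at >= 90% identity over an alignment spanning >= 40% of the
shorter sequence, on either strand; otherwise it founds a new cluster.

Identity is matches / alignment columns of the best end-free alignment of
the shorter sequence against the representative (edlib infix mode) — the
shorter-sequence identity convention of cd-hit-est, deliberately not a
trimmed local alignment, so the 90% threshold is sharp for full-length
read pairs.  A shared-word prefilter (exact 14-mers, both strands) keeps
the number of alignment calls near-linear in the bin size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import edlib

from kmernorm.io import SequenceRecord

DEFAULT_IDENTITY = 0.90
DEFAULT_MIN_COV = 0.40
_WORD_SIZE = 14

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Cluster:
    """A similarity cluster; the representative is its founding (longest)
    member and stands in for the cluster in later comparisons."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _cigar_columns(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


def alignment_identity(query: str, target: str) -> tuple[float, float]:
    """Best (identity, coverage-of-query) of query against target.

    Both strands of the query are tried in edlib infix (HW) mode: the whole
    query must align, target ends are free.  Identity is matches over
    alignment columns; coverage is the aligned fraction of the query, which
    is 1.0 whenever any alignment exists.
    """
    best = (0.0, 0.0)
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["cigar"]:
            continue
        cols = _cigar_columns(res["cigar"])
        if cols == 0:
            continue
        ident = (cols - res["editDistance"]) / cols
        if ident > best[0]:
            best = (ident, 1.0)
    return best


def _matches(
    query: str, target: str, identity: float, min_cov: float
) -> bool:
    shorter = min(len(query), len(target))
    if shorter == 0:
        return False
    ident, cov = alignment_identity(query, target)
    return ident >= identity and cov * len(query) >= min_cov * shorter


def _words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1) if "N" not in seq[i : i + w]}


def cluster_bin(
    reads: Sequence[SequenceRecord],
    identity: float = DEFAULT_IDENTITY,
    min_cov: float = DEFAULT_MIN_COV,
    word_size: int = _WORD_SIZE,
) -> list[Cluster]:
    """Greedy incremental clustering of one bin's reads.

    Deterministic: reads are processed by descending length with id as the
    tie-break, and candidate clusters are tested in founding order.
    """
    order = sorted(reads, key=lambda r: (-len(r.bases), r.read_id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    word_index: dict[str, list[int]] = {}

    for rec in order:
        seq = rec.bases
        qwords = _words(seq, word_size) | _words(revcomp(seq), word_size)
        if qwords and clusters:
            candidates: set[int] = set()
            for w in qwords:
                candidates.update(word_index.get(w, ()))
        else:
            candidates = set(range(len(clusters)))  # short reads: brute force
        home: Optional[int] = None
        for ci in sorted(candidates):
            if _matches(seq, rep_seqs[ci], identity, min_cov):
                home = ci
                break
        if home is None:
            clusters.append(Cluster(rec.read_id, [rec.read_id]))
            rep_seqs.append(seq)
            ci = len(clusters) - 1
            for w in _words(seq, word_size):
                word_index.setdefault(w, []).append(ci)
        else:
            clusters[home].member_ids.append(rec.read_id)
    return clusters


def sort_clusters_unique_first(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Smallest (most unique) cluster first; ties broken by representative
    id so the order is deterministic."""
    return sorted(clusters, key=lambda c: (c.size, c.representative_id))


def write_clstr(
    clusters_per_bin: dict[int, Sequence[Cluster]], path: Union[str, Path]
) -> None:
    """Dump clusters in a cd-hit ``.clstr``-style text format."""
    with open(path, "w") as fh:
        for b in sorted(clusters_per_bin):
            for i, cl in enumerate(clusters_per_bin[b]):
                fh.write(f">Cluster bin{b}.{i}\n")
                for j, rid in enumerate(cl.member_ids):
                    star = " *" if rid == cl.representative_id else ""
                    fh.write(f"{j}\t>{rid}{star}\n")
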