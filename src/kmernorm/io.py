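"""FASTQ/FASTA input and output with mate-pair bookkeeping.

Reads from one or more libraries are concatenated under globally unique
identifiers of the form ``<library>|<ordinal>|<original_id>`` so that
identically named reads from different libraries never collide.  A sidecar
TSV maps unique ids back to their originals.  Mate-pair relationships are
kept in a symmetric pairing table; reads later removed by filters leave a
tombstone there so a surviving mate can be demoted to fragment priority
during targeted selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

VALID_LAYOUTS = ("fragment", "paired_two_file", "paired_interleaved")

_NON_ACGTN = re.compile(r"[^ACGTN]")
_SUFFIX_DIALECT = re.compile(r"^(?P<stem>.+)/(?P<mate>[12])$")
_CASAVA_DIALECT = re.compile(r"^(?P<mate>[12]):[YN]:\d+:")


class PairingError(ValueError):
    """Raised when paired input files cannot be reconciled."""


class ReadParseError(ValueError):
    """Raised for malformed FASTQ/FASTA records, naming the offending record."""


@dataclass
class SequenceRecord:
    """One sequencing read.

    ``bases`` is uppercase over {A,C,G,T,N} (other IUPAC ambiguity codes are
    mapped to N on load).  ``quals`` is the verbatim Sanger phred+33 quality
    string, or None for FASTA input.  ``mate_role`` is ``fragment``,
    ``forward`` or ``reverse``; ``partner_id`` links the other side of a
    pair and is symmetric.
    """

    read_id: str
    bases: str
    quals: Optional[str] = None
    library: str = "lib"
    mate_role: str = "fragment"
    partner_id: Optional[str] = None
    original_id: str = ""

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ReadParseError(
                f"record {self.original_id or self.read_id}: "
                f"{len(self.bases)} bases but {len(self.quals)} quality values"
            )
        if self.mate_role not in ("fragment", "forward", "reverse"):
            raise ValueError(f"bad mate_role {self.mate_role!r}")
        if (self.mate_role == "fragment") != (self.partner_id is None):
            raise ValueError(
                f"record {self.read_id}: mate_role={self.mate_role} "
                f"inconsistent with partner_id={self.partner_id}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_unambiguous(self) -> int:
        return len(self.bases) - self.bases.count("N")


class ReadSet:
    """An ordered collection of reads indexed by unique id.

    The pairing table maps read_id <-> partner_id symmetrically and may
    reference tombstoned ids (reads removed by filters) so mate status can
    still be resolved afterwards.
    """

    def __init__(self) -> None:
        self.records: dict[str, SequenceRecord] = {}
        self.pairing: dict[str, str] = {}
        self.tombstones: set[str] = set()
        self.format: str = "fastq"
        self.dialects: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records.values())

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.records

    def __getitem__(self, read_id: str) -> SequenceRecord:
        return self.records[read_id]

    def add(self, record: SequenceRecord) -> None:
        if record.read_id in self.records or record.read_id in self.tombstones:
            raise ValueError(f"duplicate read id {record.read_id}")
        self.records[record.read_id] = record
        if record.partner_id is not None:
            self.pairing[record.read_id] = record.partner_id

    def ids(self) -> list[str]:
        return list(self.records)

    def partner_of(self, read_id: str) -> Optional[str]:
        return self.pairing.get(read_id)

    def tombstone(self, read_id: str) -> None:
        """Remove a read but keep its pairing entry for mate demotion."""
        self.records.pop(read_id, None)
        self.tombstones.add(read_id)

    def check_pairing(self) -> None:
        for a, b in self.pairing.items():
            if self.pairing.get(b) != a:
                raise PairingError(f"pairing table not symmetric at {a} <-> {b}")
            if a not in self.records and a not in self.tombstones:
                raise PairingError(f"pairing table references unknown id {a}")


def _clean_bases(seq: str) -> str:
    seq = str(seq).upper()
    return _NON_ACGTN.sub("N", seq)


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line[0] == "@":
                    return "fastq"
                if line[0] == ">":
                    return "fasta"
                break
    raise ReadParseError(f"{path}: not FASTA or FASTQ")


def _parse_records(path: Path) -> Iterator[tuple[str, str, str, Optional[str]]]:
    """Yield (id, description, bases, quals) per record."""
    fmt = _sniff_format(path)
    for rec in SeqIO.parse(str(path), fmt):
        quals = None
        if fmt == "fastq":
            quals = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        yield rec.id, rec.description, _clean_bases(rec.seq), quals


def _detect_dialect(name: str, description: str) -> tuple[str, str, Optional[str]]:
    """Return (stem, dialect, mate) from a read name and its description line.

    Dialects: ``suffix`` ("/1", "/2"), ``casava`` (" 1:N:0:..." in the
    description), ``plain`` (no mate encoding in the name).
    """
    m = _SUFFIX_DIALECT.match(name)
    if m:
        return m.group("stem"), "suffix", m.group("mate")
    rest = description[len(name):].strip() if description.startswith(name) else ""
    m = _CASAVA_DIALECT.match(rest)
    if m:
        return name, "casava", m.group("mate")
    return name, "plain", None


def load_reads(
    paths: Sequence[str | Path],
    layout: str,
    library: Optional[str] = None,
) -> ReadSet:
    """Load one library of reads.

    ``layout`` is ``fragment`` (any number of files, no pairing),
    ``paired_two_file`` (exactly two files, records paired positionally) or
    ``paired_interleaved`` (one file, consecutive records are mates).
    """
    if layout not in VALID_LAYOUTS:
        raise ValueError(f"layout must be one of {VALID_LAYOUTS}, got {layout!r}")
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if library is None:
        library = paths[0].stem

    rs = ReadSet()
    rs.format = _sniff_format(paths[0])

    def uid(ordinal: int, original: str) -> str:
        return f"{library}|{ordinal}|{original}"

    if layout == "fragment":
        n = 0
        for p in paths:
            for name, desc, bases, quals in _parse_records(p):
                stem, dialect, _ = _detect_dialect(name, desc)
                rs.dialects.setdefault(library, dialect)
                rs.add(
                    SequenceRecord(
                        read_id=uid(n, name),
                        bases=bases,
                        quals=quals,
                        library=library,
                        original_id=name,
                    )
                )
                n += 1
        return rs

    if layout == "paired_two_file":
        if len(paths) != 2:
            raise PairingError("paired_two_file layout needs exactly two files")
        r1 = list(_parse_records(paths[0]))
        r2 = list(_parse_records(paths[1]))
        if len(r1) != len(r2):
            raise PairingError(
                f"unequal mate files: {paths[0]} has {len(r1)} records, "
                f"{paths[1]} has {len(r2)}"
            )
        for i, ((n1, d1, b1, q1), (n2, d2, b2, q2)) in enumerate(zip(r1, r2)):
            stem1, dialect, _ = _detect_dialect(n1, d1)
            stem2, _, _ = _detect_dialect(n2, d2)
            if stem1 != stem2:
                raise PairingError(
                    f"record {i}: mate names {n1!r} and {n2!r} do not share a stem"
                )
            rs.dialects.setdefault(library, dialect)
            id_f, id_r = uid(2 * i, n1), uid(2 * i + 1, n2)
            rs.add(SequenceRecord(id_f, b1, q1, library, "forward", id_r, n1))
            rs.add(SequenceRecord(id_r, b2, q2, library, "reverse", id_f, n2))
        return rs

    # paired_interleaved
    if len(paths) != 1:
        raise PairingError("paired_interleaved layout takes a single file")
    recs = list(_parse_records(paths[0]))
    if len(recs) % 2:
        raise PairingError(f"{paths[0]}: odd record count in interleaved file")
    for i in range(0, len(recs), 2):
        (n1, d1, b1, q1), (n2, d2, b2, q2) = recs[i], recs[i + 1]
        stem1, dialect, _ = _detect_dialect(n1, d1)
        stem2, _, _ = _detect_dialect(n2, d2)
        if stem1 != stem2:
            raise PairingError(
                f"records {i},{i + 1}: interleaved mates {n1!r}/{n2!r} "
                f"do not share a stem"
            )
        rs.dialects.setdefault(library, dialect)
        id_f, id_r = uid(i, n1), uid(i + 1, n2)
        rs.add(SequenceRecord(id_f, b1, q1, library, "forward", id_r, n1))
        rs.add(SequenceRecord(id_r, b2, q2, library, "reverse", id_f, n2))
    return rs


def merge_readsets(readsets: Iterable[ReadSet]) -> ReadSet:
    """Concatenate libraries into one set; ids must already be unique."""
    out = ReadSet()
    first = True
    for rs in readsets:
        if first:
            out.format = rs.format
            first = False
        for rec in rs:
            out.add(rec)
        out.tombstones |= rs.tombstones
        out.pairing.update(rs.pairing)
        out.dialects.update(rs.dialects)
    out.check_pairing()
    return out


def parse_pairs(
    selected_ids: Iterable[str], pairing: dict[str, str]
) -> tuple[set[tuple[str, str]], set[str]]:
    """Partition a selection into two-sided pairs and single reads.

    A pair is reported (as an id tuple in sorted order) iff both partners
    are selected; every other selected read is a single.  This is the
    post-hoc mate parsing used after fragment-mode runs.
    """
    sel = set(selected_ids)
    pairs: set[tuple[str, str]] = set()
    singles: set[str] = set()
    for rid in sel:
        mate = pairing.get(rid)
        if mate is not None and mate in sel:
            pairs.add((rid, mate) if rid < mate else (mate, rid))
        else:
            singles.add(rid)
    return pairs, singles


def _format_record(rec: SequenceRecord, fmt: str) -> str:
    if fmt == "fastq":
        quals = rec.quals if rec.quals is not None else "I" * len(rec.bases)
        return f"@{rec.read_id}\n{rec.bases}\n+\n{quals}\n"
    return f">{rec.read_id}\n{rec.bases}\n"


def write_selection(
    readset: ReadSet,
    selected_ids: Iterable[str],
    out_prefix: str | Path,
    write_empty: bool = True,
) -> dict[str, Path]:
    """Write the selected reads, split into pair and fragment files.

    ``PREFIX.paired.<ext>`` holds, interleaved, only the pairs where both
    mates were selected; ``PREFIX.fragments.<ext>`` holds every other
    selected read.  Output format mirrors the input format and qualities
    are preserved verbatim.
    """
    sel = set(selected_ids)
    missing = sel - set(readset.records)
    if missing:
        raise KeyError(f"selected ids not in read set: {sorted(missing)[:5]}")
    fmt = readset.format
    ext = "fastq" if fmt == "fastq" else "fasta"
    pairs, singles = parse_pairs(sel, readset.pairing)

    out_prefix = Path(out_prefix)
    paired_path = out_prefix.with_name(out_prefix.name + f".paired.{ext}")
    frag_path = out_prefix.with_name(out_prefix.name + f".fragments.{ext}")
    out: dict[str, Path] = {}

    # keep input order within each file for reproducibility
    order = {rid: i for i, rid in enumerate(readset.records)}
    if pairs or write_empty:
        with open(paired_path, "w") as fh:
            for a, b in sorted(pairs, key=lambda p: order[p[0]]):
                fwd, rev = (a, b) if readset[a].mate_role == "forward" else (b, a)
                fh.write(_format_record(readset[fwd], fmt))
                fh.write(_format_record(readset[rev], fmt))
        out["paired"] = paired_path
    if singles or write_empty:
        with open(frag_path, "w") as fh:
            for rid in sorted(singles, key=order.__getitem__):
                fh.write(_format_record(readset[rid], fmt))
        out["fragments"] = frag_path
    return out


def write_id_map(readset: ReadSet, path: str | Path) -> None:
    """Sidecar TSV mapping unique ids back to library and original id."""
    with open(path, "w") as fh:
        fh.write("unique_id\tlibrary\toriginal_id\n")
        for rec in readset:
            fh.write(f"{rec.read_id}\t{rec.library}\t{rec.original_id}\n")
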