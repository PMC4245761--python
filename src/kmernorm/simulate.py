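"""Synthetic amplification-biased read sets with known ground truth.

Random-primed amplification (MDA of single cells, SISPA of viral samples)
yields coverage profiles with deep spikes — hundreds-fold over the mean —
beside near-zero troughs.  The generator here reproduces that shape
directly: the genome is tiled into fixed-length windows, each with a
target mean depth, and read (or fragment) start positions are drawn
per-window in proportion to that depth.  Optional per-window log-normal
multipliers give a continuous bias texture on top of hard spikes and
troughs.  Substitution errors and paired-end layout with Gaussian inserts
are supported; every read carries truth (origin, strand, window, repeat
flag) so downstream depth metrics need no aligner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from kmernorm.clustering import revcomp
from kmernorm.io import ReadSet, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass
class RepeatSpec:
    """Copy ``length`` bases starting at ``source_start`` onto
    ``target_start``, creating an exact two-copy repeat."""

    source_start: int
    length: int
    target_start: int


@dataclass
class CoverageProfile:
    """Per-window target mean depth; windows tile the genome."""

    window_len: int
    depths: list[float]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValueError("window depths must be >= 0")

    @property
    def genome_len(self) -> int:
        return self.window_len * len(self.depths)

    def window_of(self, pos: int) -> int:
        return min(pos // self.window_len, len(self.depths) - 1)

    @classmethod
    def uniform(cls, genome_len: int, window_len: int, depth: float) -> "CoverageProfile":
        return cls(window_len, [depth] * (genome_len // window_len))

    @classmethod
    def two_tier(
        cls,
        genome_len: int,
        window_len: int,
        high_depth: float,
        low_depth: float,
        high_fraction: float = 0.1,
    ) -> "CoverageProfile":
        """A block of high-depth windows at the start, low depth elsewhere."""
        n = genome_len // window_len
        n_high = max(1, round(n * high_fraction))
        return cls(window_len, [high_depth] * n_high + [low_depth] * (n - n_high))

    @classmethod
    def lognormal(
        cls,
        genome_len: int,
        window_len: int,
        base_depth: float,
        sigma: float,
        seed: int,
        spikes: Sequence[tuple[int, int, float]] = (),
    ) -> "CoverageProfile":
        """Log-normal per-window bias around ``base_depth`` plus hard
        (start_window, end_window, depth) overrides for spikes/troughs."""
        rng = np.random.default_rng(seed)
        n = genome_len // window_len
        mult = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)
        depths = (base_depth * mult).tolist()
        for w0, w1, d in spikes:
            for w in range(w0, min(w1, n)):
                depths[w] = d
        return cls(window_len, depths)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("window_start\twindow_end\tdepth\n")
            for i, d in enumerate(self.depths):
                fh.write(f"{i * self.window_len}\t{(i + 1) * self.window_len}\t{d}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CoverageProfile":
        starts, ends, depths = [], [], []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                starts.append(int(row["window_start"]))
                ends.append(int(row["window_end"]))
                depths.append(float(row["depth"]))
        if not starts:
            raise ValueError(f"{path}: empty coverage profile")
        window_len = ends[0] - starts[0]
        return cls(window_len, depths)


@dataclass
class ReadTruth:
    read_id: str
    start: int
    end: int
    strand: str
    window: int
    in_repeat: bool = False


@dataclass
class SimulatedReadSet:
    """A ReadSet plus per-read origin truth."""

    reads: ReadSet
    truth: dict[str, ReadTruth] = field(default_factory=dict)
    genome: str = ""
    profile: Optional[CoverageProfile] = None

    def truth_to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tstart\tend\tstrand\twindow\tin_repeat\n")
            for t in self.truth.values():
                fh.write(
                    f"{t.read_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                    f"{t.window}\t{int(t.in_repeat)}\n"
                )

    @staticmethod
    def truth_from_tsv(path: Union[str, Path]) -> dict[str, ReadTruth]:
        truth: dict[str, ReadTruth] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                truth[row["read_id"]] = ReadTruth(
                    read_id=row["read_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    window=int(row["window"]),
                    in_repeat=bool(int(row["in_repeat"])),
                )
        return truth


def make_genome(
    length: int,
    gc: float = 0.5,
    repeat_spec: Optional[RepeatSpec] = None,
    seed: int = 0,
) -> str:
    """Seeded random genome with the given GC content; ``repeat_spec``
    overwrites a second locus with an exact copy of a source segment."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p)
    if repeat_spec is not None:
        r = repeat_spec
        if r.target_start + r.length > length or r.source_start + r.length > length:
            raise ValueError("repeat segment extends past the genome end")
        seq[r.target_start : r.target_start + r.length] = seq[
            r.source_start : r.source_start + r.length
        ]
    return "".join(seq)


def _apply_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < err_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _repeat_overlaps(start: int, end: int, repeat: Optional[RepeatSpec]) -> bool:
    if repeat is None:
        return False
    for s in (repeat.source_start, repeat.target_start):
        if start < s + repeat.length and end > s:
            return True
    return False


def simulate_reads(
    genome: str,
    profile: CoverageProfile,
    read_len: int = 100,
    paired: bool = False,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    err_rate: float = 0.0,
    seed: int = 0,
    library: str = "sim",
    repeat_spec: Optional[RepeatSpec] = None,
) -> SimulatedReadSet:
    """Draw reads window by window in proportion to the target depth.

    Fragment mode emits ``round(depth * window_len / read_len)`` reads per
    window on a uniformly random strand; paired mode emits half as many
    fragments, each contributing a forward/reverse mate pair with a
    Gaussian insert (truncated below at the read length).
    """
    if profile.genome_len > len(genome):
        raise ValueError("profile tiles more sequence than the genome has")
    if paired and insert_mean < read_len:
        raise ValueError(f"insert_mean {insert_mean} < read_len {read_len}")
    if read_len > len(genome):
        raise ValueError("read_len exceeds the genome length")

    rng = np.random.default_rng(seed)
    glen = len(genome)
    rs = ReadSet()
    rs.format = "fasta"
    sim = SimulatedReadSet(reads=rs, genome=genome, profile=profile)
    ordinal = 0

    def emit(name: str, start: int, strand: str, role: str, partner: Optional[str], window: int) -> str:
        nonlocal ordinal
        rid = f"{library}|{ordinal}|{name}"
        ordinal += 1
        frag = genome[start : start + read_len]
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_errors(frag, err_rate, rng)
        rs.add(
            SequenceRecord(
                read_id=rid,
                bases=frag,
                library=library,
                mate_role=role,
                partner_id=partner,
                original_id=name,
            )
        )
        sim.truth[rid] = ReadTruth(
            read_id=rid,
            start=start,
            end=start + read_len,
            strand=strand,
            window=window,
            in_repeat=_repeat_overlaps(start, start + read_len, repeat_spec),
        )
        return rid

    serial = 0
    for w, depth in enumerate(profile.depths):
        w0 = w * profile.window_len
        w1 = min((w + 1) * profile.window_len, glen)
        per_read_bases = 2 * read_len if paired else read_len
        n = int(round(depth * (w1 - w0) / per_read_bases))
        for _ in range(n):
            if paired:
                insert = int(round(rng.normal(insert_mean, insert_sd)))
                insert = max(read_len, insert)
                s = int(rng.integers(w0, w1))
                s = max(0, min(s, glen - insert))
                name = f"p{serial:07d}"
                serial += 1
                # forward/reverse roles; both mates point at each other
                fid = f"{library}|{ordinal}|{name}/1"
                rid2 = f"{library}|{ordinal + 1}|{name}/2"
                for start, strand, role, me, partner, nm in (
                    (s, "+", "forward", fid, rid2, f"{name}/1"),
                    (s + insert - read_len, "-", "reverse", rid2, fid, f"{name}/2"),
                ):
                    got = emit(nm, start, strand, role, partner, w)
                    assert got == me
            else:
                s = int(rng.integers(w0, w1))
                s = max(0, min(s, glen - read_len))
                strand = "+" if rng.integers(2) == 0 else "-"
                emit(f"f{serial:07d}", s, strand, "fragment", None, w)
                serial += 1
    rs.check_pairing()
    return sim


def write_fasta(sim: SimulatedReadSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in sim.reads:
            fh.write(f">{rec.read_id}\n{rec.bases}\n")
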